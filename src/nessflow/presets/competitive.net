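species A init=1 exchanged inflow=1
species C init=0 exchanged inflow=0
species D init=0 exchanged inflow=0
reaction RC: A <-> C ; kf=10, kr=1
reaction RD: A <-> D ; kf=1, kr=0.10000000000000001
system T=300 flow=1
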