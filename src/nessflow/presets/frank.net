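species A init=1 exchanged inflow=1
species L init=0.01 exchanged inflow=0
species D init=0.01 exchanged inflow=0
species P init=0 exchanged inflow=0
reaction PL: A <-> L ; kf=0.5, kr=0.0050000000000000001
reaction PD: A <-> D ; kf=0.5, kr=0.0050000000000000001
reaction AL: A + L <-> 2 L ; kf=2, kr=0.02
reaction AD: A + D <-> 2 D ; kf=2, kr=0.02
reaction IN: D + L <-> P ; kf=10, kr=0.10000000000000001
system T=300 flow=0.14999999999999999
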