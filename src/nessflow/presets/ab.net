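species A init=1
species B init=0
reaction R1: A <-> B ; kf=2, kr=1
system T=300 flow=0
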