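species A init=1 clamped
species X init=0.5
species B init=1 clamped
reaction R1: A <-> X ; kf=6, kr=11
reaction R2: 3 X <-> B + 2 X ; kf=1, kr=6
system T=300 flow=0
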