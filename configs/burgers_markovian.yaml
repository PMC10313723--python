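# Shock truncation-error discovery over three (Nx, Re) training pairs.
experiment: burgers_markovian
seeds: [0]
t_max: 3.0
epochs: 200
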