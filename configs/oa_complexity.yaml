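# NPZ-OA complexity augmentation: staged Markovian + delay-kernel closures.
experiment: oa_complexity
seeds: [0]
days: 60.0
epochs: 200
kernel_epochs: 100
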