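# Closure-recovery harness with a known planted diffusion term.
experiment: planted_recovery
c_star: 0.7
seed: 0
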