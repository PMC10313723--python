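# Two-soliton dispersion discovery: library closure on the advection-only
# low-fidelity model (truth: u_t = -6 u u_x - u_xxx).
experiment: kdv_discovery
seeds: [0, 1, 2]
Nx: 200
epochs: 240
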