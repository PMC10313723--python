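# Zooplankton-mortality functional-form discrimination (NPZD-OA column).
experiment: oa_discrimination
seeds: [0, 1, 2]
days: 30.0
epochs: 220
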