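# Scaled-down operating-characteristics run: continuous endpoint, max n = 100,
# null effect, correct vs unadjusted analysis models.
builtin: continuous_ss100_null
models: [correct, unadjusted]
replicates: 400
master_seed: 1
sampler:
  chains: 3
  draws: 1000
# quarter the replicate count and draw budget for a quick pass
scaled: true
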