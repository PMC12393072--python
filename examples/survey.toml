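# 13-sensor sensitivity survey: 5 uninfested + 5 infested fruits,
# deterministic quantile draws at the catalogued group effect sizes
mode = "survey"
seed = 0
alpha = 0.05

[design]
draw = "quantile"
noise_sd = 0.0
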