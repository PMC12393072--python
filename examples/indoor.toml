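# indoor daily ripening of 6 fruits over 7 days, cracking on day 4
mode = "indoor"
seed = 1
n_permutations = 199
coverage = 0.95
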