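# outdoor 3-class detection: train LDA on 990 readings, test on 300
mode = "outdoor"
seed = 1
n_permutations = 199
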