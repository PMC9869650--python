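fold_class,n_chains
mainly-alpha,70
mainly-beta,282
alpha-beta,196
special,47
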