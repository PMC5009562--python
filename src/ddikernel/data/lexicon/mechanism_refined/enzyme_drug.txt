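# The action of an enzyme on a drug
catalyze
catalyzes
metabolize
oxidize
demethylate
hydroxylate
deacetylate
conjugate
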