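# Trigger words related to DDI mechanisms (superset of the refined subclasses)
stimulate
inhibit
inhibition
induce
inactivate
block
suppress
potentiate
catalyze
catalyzes
metabolize
oxidize
demethylate
hydroxylate
deacetylate
conjugate
hydroxylation
4-hydroxylation
demethylation
oxidation
glucuronidation
deacetylation
dealkylation
methylation
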