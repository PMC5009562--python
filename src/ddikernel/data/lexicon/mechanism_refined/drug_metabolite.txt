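# The action converting a drug to its metabolite
hydroxylation
4-hydroxylation
demethylation
oxidation
glucuronidation
deacetylation
dealkylation
methylation
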