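# Doses, sample sizes, PK-parameter values (matched against full tokens)
[0-9]+(\.[0-9]+)?
[0-9]+(\.[0-9]+)?\s*%
[0-9]+(\.[0-9]+)?[–-][0-9]+(\.[0-9]+)?\s*%?
%
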