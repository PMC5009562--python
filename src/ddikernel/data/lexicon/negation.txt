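# Negative expressions (illustrative starter list)
negligible
not
no
neither
nor
without
fail
lack
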