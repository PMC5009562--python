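# Change of PK parameters (illustrative starter list)
decrease
increase
elevate
reduce
augment
diminish
raise
lower
boost
attenuate
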