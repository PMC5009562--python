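# CYP450 enzymes (illustrative starter list)
cyp1a2
cyp2c9
cyp2c19
cyp2d6
cyp3a4
p-glycoprotein
esterase
microsome
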