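# Pharmacokinetic parameters (illustrative starter list)
auc
cmax
tmax
clearance
half-life
bioavailability
exposure
plasma concentration
concentration
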