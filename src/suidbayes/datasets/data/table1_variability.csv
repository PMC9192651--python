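subcategory,mean,sd,cv_printed
SIDS,0.11,0.08,72.7
asphyxia,0.07,0.05,71.4
unknown,0.31,0.10,32.2
SUID,0.49,0.09,18.4
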