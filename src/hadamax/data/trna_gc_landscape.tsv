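genotype	phenotype	error
GC	0	0.01
GA	-0.14	0.05
GT	-0.07	0.02
AC	-0.13	0.02
AA	-0.8	0.15
AT	-0.01	0.03
TC	-0.19	0.02
TA	0	0.04
TT	-0.18	0.03
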