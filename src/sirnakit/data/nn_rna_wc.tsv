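# Watson-Crick RNA nearest-neighbor increments, 1 M NaCl reference.
# stack XY denotes the 5'->3' dinucleotide XY paired with its reverse
# complement on the antiparallel strand (XY/complement).  The 10 entries
# are unique under reverse-complement symmetry; the loader resolves all 16.
stack	dH_kcal_mol	dS_cal_molK
AA	-6.82	-19.0
AU	-9.38	-26.7
UA	-7.69	-20.5
CU	-10.48	-27.1
CA	-10.44	-26.9
GU	-11.40	-29.5
GA	-12.44	-32.5
CG	-10.64	-26.7
GG	-13.39	-32.7
GC	-14.88	-36.9
init	3.61	-1.5
terminal_AU	3.72	10.5
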