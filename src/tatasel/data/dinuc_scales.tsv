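# Dinucleotide property scales used by the context terms of the affinity model.
# ta_richness: fraction of A/T bases in the step (1, 0.5 or 0).
# minor_groove_width: B-DNA minor-groove width in angstroms (packaged defaults;
#   A/T-rich steps narrow, G/C-rich steps wide).
# melting: nearest-neighbour duplex stability, unified dG37 in kcal/mol
#   (less negative = easier local melting).
# All three scales are reverse-complement symmetric.
dinuc	ta_richness	minor_groove_width	melting
AA	1.0	4.0	-1.00
AC	0.5	4.8	-1.44
AG	0.5	4.6	-1.28
AT	1.0	3.6	-0.88
CA	0.5	5.3	-1.45
CC	0.0	5.1	-1.84
CG	0.0	5.6	-2.17
CT	0.5	4.6	-1.28
GA	0.5	5.0	-1.30
GC	0.0	5.5	-2.24
GG	0.0	5.1	-1.84
GT	0.5	4.8	-1.44
TA	1.0	5.0	-0.58
TC	0.5	5.0	-1.30
TG	0.5	5.3	-1.45
TT	1.0	4.0	-1.00
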