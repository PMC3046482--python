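# Two-color RNA-FISH in female fibroblasts: counts of nuclei expressing one or
# both of two neighboring X-borne loci (A and B) from the inactive X, among the
# ~100 nuclei scored per pair in which at least one test locus showed two
# signals. b_only = signal on Xi for B but not A (-/+), a_only = A but not B
# (+/-), both = concordant escape (+/+). Row sums reflect the published counts
# (LRCH2/WDR44 sums to 101, TMLHE pair to 99, as printed).
locus_a	locus_b	b_only	a_only	both
AMOT	WDR44	60	40	0
LRCH2	WDR44	27	74	0
TMLHE	MECP2X_IRAK1_TMEM187	39	36	24
PSMD10	STAG2	57	42	1
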