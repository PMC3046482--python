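# Female tammar wallaby fibroblast RNA-FISH scoring: percent of diploid nuclei
# (two autosomal GBA control signals) with two / one / zero signals for each
# X-borne probe. At least 100 diploid nuclei were scored per probe; where raw
# counts are needed they are reconstructed from these percentages by
# largest-remainder apportionment at the nominal n = 100.
locus_id	pct_2_signals	pct_1_signal	pct_0_signals
G6PD_IKBKG	17.0	82.0	1.0
TMLHE	29.0	68.0	3.0
RPL10X	27.0	71.0	2.0
MECP2X_IRAK1_TMEM187	41.0	54.0	5.0
HCFC1X	7.0	91.0	2.0
AR	9.0	87.0	4.0
PSMD10	6.7	93.3	0.0
STAG2	6.7	92.0	1.3
HPRT_PHF6X	23.5	73.5	3.1
UPF3B	11.7	86.7	1.7
PGK1	18.5	80.4	1.1
ATRX	59.8	39.2	1.0
RBMX	11.0	87.0	2.0
UBA1_RBM10	67.8	32.2	0.0
TBC1D25_GATA1	14.3	84.7	1.0
GATA1_WDR13	14.9	81.3	3.7
GLA_GLRA4	7.5	89.2	3.2
KDM5C	35.0	65.0	0.0
HUWE1X	15.0	85.0	0.0
AKAP4	44.1	51.0	4.9
AMOT	23.0	71.7	5.3
LRCH2	5.2	92.8	2.1
WDR44	14.3	81.6	4.1
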