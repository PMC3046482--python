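# Male tammar wallaby fibroblast RNA-FISH scoring: percent of diploid nuclei
# (two autosomal GBA control signals) showing one signal for each X-borne probe.
# At least 100 diploid nuclei were scored per probe; counts are reconstructed
# at the nominal n = 100. F9 and PLP1 showed no signal (not expressed in
# fibroblasts) and are excluded from downstream escape analysis.
locus_id	pct_one_signal
G6PD_IKBKG	95
TMLHE	96
RPL10X	98
MECP2X_IRAK1_TMEM187	99
HCFC1X	99
AR	94
PSMD10	98
STAG2	95
HPRT_PHF6X	95
F9	0
UPF3B	99
PGK1	98
ATRX	98
RBMX	95
UBA1_RBM10	98
TBC1D25_GATA1	98
GATA1_WDR13	94
GLA_GLRA4	98
PLP1	0
KDM5C	96
HUWE1X	97
AKAP4	99
LRCH2	96
WDR44	94
AMOT	95
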