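# Probe/locus metadata for the 25 X-borne BAC/fosmid probes (32 genes) assayed
# on the tammar wallaby X. Row order is the published centromere-down gene
# order on the X. SYNTHETIC COORDINATES: the published per-clone genome
# coordinates are not reproduced here; start/end are evenly spaced synthetic
# placeholders (0-based half-open, ~200 kb clones) that preserve the published
# order, and clone_id values are synthetic placeholders. Positional statistics
# in this package are rank-based, so they depend only on the order.
# y_paralogue: expressed / silent from the X-vs-Y two-color assay; none = no
# known fibroblast-assayed Y paralogue.
locus_id	genes	clone_id	chrom	start	end	y_paralogue	human_band
G6PD_IKBKG	G6PD,IKBKG	synthetic-clone-01	X	2000000	2200000	none	.
TMLHE	TMLHE	synthetic-clone-02	X	5000000	5200000	none	.
RPL10X	RPL10X	synthetic-clone-03	X	8000000	8200000	expressed	.
MECP2X_IRAK1_TMEM187	MECP2X,IRAK1,TMEM187	synthetic-clone-04	X	11000000	11200000	expressed	.
HCFC1X	HCFC1X	synthetic-clone-05	X	14000000	14200000	expressed	.
AR	AR	synthetic-clone-06	X	17000000	17200000	none	.
PSMD10	PSMD10	synthetic-clone-07	X	20000000	20200000	none	.
STAG2	STAG2	synthetic-clone-08	X	23000000	23200000	none	.
HPRT_PHF6X	HPRT,PHF6X	synthetic-clone-09	X	26000000	26200000	silent	.
F9	F9	synthetic-clone-10	X	29000000	29200000	none	.
UPF3B	UPF3B	synthetic-clone-11	X	32000000	32200000	none	.
PGK1	PGK1	synthetic-clone-12	X	35000000	35200000	none	.
ATRX	ATRX	synthetic-clone-13	X	38000000	38200000	silent	.
RBMX	RBMX	synthetic-clone-14	X	41000000	41200000	silent	.
UBA1_RBM10	UBA1,RBM10	synthetic-clone-15	X	44000000	44200000	none	.
TBC1D25_GATA1	TBC1D25,GATA1	synthetic-clone-16	X	47000000	47200000	none	.
GATA1_WDR13	GATA1,WDR13	synthetic-clone-17	X	50000000	50200000	none	.
GLA_GLRA4	GLA,GLRA4	synthetic-clone-18	X	53000000	53200000	none	.
PLP1	PLP1	synthetic-clone-19	X	56000000	56200000	none	.
KDM5C	KDM5C	synthetic-clone-20	X	59000000	59200000	none	.
HUWE1X	HUWE1X	synthetic-clone-21	X	62000000	62200000	expressed	.
AKAP4	AKAP4	synthetic-clone-22	X	65000000	65200000	none	.
LRCH2	LRCH2	synthetic-clone-23	X	68000000	68200000	none	.
WDR44	WDR44	synthetic-clone-24	X	71000000	71200000	none	.
AMOT	AMOT	synthetic-clone-25	X	74000000	74200000	none	.
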