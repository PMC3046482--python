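# X-borne genes with Y-chromosome paralogues: fibroblast expression status of
# the Y copy (two-color RNA-FISH, male nuclei) contrasted with the X copy's
# escape-from-inactivation band (percent of 2X-active female nuclei).
gene_pair	locus_id	y_copy_expression	escape_band
ATRX/ATRY	ATRX	not_expressed	>50%
RBMX/RBMY	RBMX	not_expressed	0-25%
PHF6X/PHF6Y	HPRT_PHF6X	not_expressed	0-25%
HUWE1X/HUWE1Y	HUWE1X	expressed	0-25%
RPL10X/RPL10Y	RPL10X	expressed	25-50%
HCFC1X/HCFC1Y	HCFC1X	expressed	0-25%
MECP2X/MECP2Y	MECP2X_IRAK1_TMEM187	expressed	25-50%
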