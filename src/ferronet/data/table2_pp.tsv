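gene_id	function	mean_ratio	sd_ratio	alias
AT2G01880	PAP7 (PURPLE ACID PHOSPHATASE 7); acid phosphatase/protein serine/threonine phosphatase	3.11	0.42	PAP7
AT2G32960	Tyrosine specific protein phosphatase family protein	1.95	0.19	PFA-DSP2
AT3G49370	CDPK-related kinase	1.71	0.30
AT2G01890	PAP8 (PURPLE ACID PHOSPHATASE 8); acid phosphatase/protein serine/threonine phosphatase	1.57	0.04	PAP8
AT2G46700	CDPK-related kinase	1.52	0.11	CRK3
AT5G26010	Catalytic/protein serine/threonine phosphatase	0.65	0.07
AT5G59220	Protein phosphatase 2C, putative/PP2C, putative	0.45	0.04	SAG113
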