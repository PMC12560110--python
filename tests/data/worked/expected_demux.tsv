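contig_id	strain	rule_fired
d_above	A	ABOVE_BAND
d_band_uniform	A	BAND_UNIFORM
d_below	B	BELOW_BAND
d_zero	B	BELOW_BAND
d_band_localized	B	BAND_LOCALIZED
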