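f_pass	Cardinium
f_len	Cardinium
f_len_edge	Cardinium
f_gc	Cardinium
f_gc_edge	Cardinium
f_host	host
f_cov	Cardinium
f_cov_edge	Cardinium
f_len_gc	Cardinium
d_above	Cardinium
d_band_uniform	Cardinium
d_below	Cardinium
d_zero	Cardinium
d_band_localized	Cardinium
p_plasmid	Cardinium
p_chrom	Cardinium
p_small	Cardinium
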