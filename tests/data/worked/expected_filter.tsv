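contig_id	kept	reasons
f_pass	true	
f_len	false	LEN
f_len_edge	true	
f_gc	false	GC
f_gc_edge	true	
f_tax	false	TAX
f_host	false	GC,TAX
f_cov	false	COV
f_cov_edge	true	
f_len_gc	false	LEN,GC
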