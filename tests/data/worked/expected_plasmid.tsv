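contig_id	flagged
p_plasmid	true
p_chrom	false
p_small	false
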