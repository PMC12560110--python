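##gff-version 3
p_plasmid	symcurate	CDS	101	1000	.	+	.	ID=feat1;product=plasmid partitioning protein ParA
p_plasmid	symcurate	CDS	1101	2000	.	-	.	ID=feat2;product=ParB family partition protein
p_plasmid	symcurate	CDS	2101	3000	.	+	.	ID=feat3;product=hypothetical protein
p_plasmid	symcurate	CDS	3101	4000	.	+	.	ID=feat4;product=hypothetical protein
p_plasmid	symcurate	CDS	4101	5000	.	-	.	ID=feat5;product=hypothetical protein
p_plasmid	symcurate	CDS	5101	5700	.	+	.	ID=feat6;product=hypothetical protein
p_plasmid	symcurate	CDS	5701	5990	.	+	.	ID=feat7;product=IS110 family transposase
p_chrom	symcurate	CDS	101	1000	.	+	.	ID=feat8;product=30S ribosomal protein S3
p_chrom	symcurate	CDS	1101	2000	.	+	.	ID=feat9;product=DNA gyrase subunit A
p_chrom	symcurate	CDS	2101	3000	.	-	.	ID=feat10;product=elongation factor Tu
p_chrom	symcurate	CDS	3101	4000	.	+	.	ID=feat11;product=hypothetical protein
p_small	symcurate	CDS	101	1000	.	+	.	ID=feat12;product=ParA family protein
p_small	symcurate	CDS	1101	2000	.	+	.	ID=feat13;product=hypothetical protein
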