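##gff-version 3
##sequence-region chr1 1 1000
chr1	toy	gene	100	200	.	+	.	ID=gene1
chr1	toy	gene	300	400	.	-	.	ID=gene2
chr1	toy	gene	500	550	.	+	.	ID=gene3;Part=1
chr1	toy	gene	600	650	.	+	.	ID=gene3;Part=2
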