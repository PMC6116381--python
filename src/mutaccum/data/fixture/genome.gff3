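##gff-version 3
##sequence-region synthetic_42 1 20000
synthetic_42	mutaccum	CDS	204	1415	.	+	0	ID=gene_0001
synthetic_42	mutaccum	CDS	1619	2830	.	-	0	ID=gene_0002
synthetic_42	mutaccum	CDS	3033	4244	.	+	0	ID=gene_0003
synthetic_42	mutaccum	CDS	4447	5658	.	-	0	ID=gene_0004
synthetic_42	mutaccum	CDS	5861	7072	.	+	0	ID=gene_0005
synthetic_42	mutaccum	CDS	7275	8486	.	-	0	ID=gene_0006
synthetic_42	mutaccum	CDS	8689	9900	.	+	0	ID=gene_0007
synthetic_42	mutaccum	CDS	10103	11314	.	-	0	ID=gene_0008
synthetic_42	mutaccum	CDS	11517	12728	.	+	0	ID=gene_0009
synthetic_42	mutaccum	CDS	12931	14142	.	-	0	ID=gene_0010
synthetic_42	mutaccum	CDS	14345	15556	.	+	0	ID=gene_0011
synthetic_42	mutaccum	CDS	15759	16970	.	-	0	ID=gene_0012
synthetic_42	mutaccum	CDS	17173	18384	.	+	0	ID=gene_0013
synthetic_42	mutaccum	CDS	18587	19798	.	-	0	ID=gene_0014
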