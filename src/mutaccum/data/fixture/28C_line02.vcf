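##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	165	.	G	A	.	PASS	DP=140
synthetic_42	772	.	G	A	.	PASS	DP=147
synthetic_42	1090	.	C	T	.	PASS	DP=165
synthetic_42	2862	.	G	A	.	PASS	DP=167
synthetic_42	3120	.	C	T	.	PASS	DP=181
synthetic_42	6681	.	C	T	.	PASS	DP=141
synthetic_42	6727	.	T	C	.	PASS	DP=176
synthetic_42	7673	.	A	G	.	PASS	DP=174
synthetic_42	10365	.	G	A	.	PASS	DP=168
synthetic_42	13171	.	C	A	.	PASS	DP=182
synthetic_42	13639	.	G	A	.	PASS	DP=154
synthetic_42	14498	.	A	G	.	PASS	DP=173
synthetic_42	15872	.	G	A	.	PASS	DP=177
synthetic_42	16198	.	A	G	.	PASS	DP=161
synthetic_42	17770	.	C	CC	.	PASS	DP=154
synthetic_42	18807	.	T	C	.	PASS	DP=177
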