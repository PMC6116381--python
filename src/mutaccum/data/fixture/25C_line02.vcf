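##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	2604	.	C	T	.	PASS	DP=157
synthetic_42	5630	.	G	GG	.	PASS	DP=193
synthetic_42	6388	.	C	T	.	PASS	DP=188
synthetic_42	6584	.	G	A	.	PASS	DP=157
synthetic_42	7624	.	G	A	.	PASS	DP=162
synthetic_42	7857	.	G	A	.	PASS	DP=152
synthetic_42	8673	.	T	C	.	PASS	DP=161
synthetic_42	9446	.	G	A	.	PASS	DP=153
synthetic_42	10164	.	T	C	.	PASS	DP=158
synthetic_42	11265	.	G	A	.	PASS	DP=180
synthetic_42	11330	.	T	C	.	PASS	DP=167
synthetic_42	11391	.	C	CC	.	PASS	DP=165
synthetic_42	11733	.	A	G	.	PASS	DP=162
synthetic_42	12983	.	G	A	.	PASS	DP=156
synthetic_42	13021	.	T	C	.	PASS	DP=156
synthetic_42	13449	.	C	T	.	PASS	DP=162
synthetic_42	13656	.	T	A	.	PASS	DP=161
synthetic_42	15697	.	T	TT	.	PASS	DP=145
synthetic_42	16520	.	AA	A	.	PASS	DP=146
synthetic_42	16649	.	G	A	.	PASS	DP=159
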