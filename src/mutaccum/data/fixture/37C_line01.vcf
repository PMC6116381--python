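##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	391	.	C	T	.	PASS	DP=174
synthetic_42	795	.	C	T	.	PASS	DP=173
synthetic_42	1054	.	C	A	.	PASS	DP=174
synthetic_42	1157	.	A	T	.	PASS	DP=165
synthetic_42	2070	.	A	G	.	PASS	DP=186
synthetic_42	2430	.	C	T	.	PASS	DP=185
synthetic_42	2835	.	G	A	.	PASS	DP=178
synthetic_42	4518	.	CC	C	.	PASS	DP=150
synthetic_42	4677	.	A	G	.	PASS	DP=164
synthetic_42	6515	.	C	T	.	PASS	DP=157
synthetic_42	7518	.	C	T	.	PASS	DP=150
synthetic_42	8485	.	A	G	.	PASS	DP=168
synthetic_42	8845	.	C	T	.	PASS	DP=160
synthetic_42	9582	.	C	T	.	PASS	DP=174
synthetic_42	9718	.	G	A	.	PASS	DP=171
synthetic_42	10847	.	G	A	.	PASS	DP=169
synthetic_42	11175	.	C	T	.	PASS	DP=149
synthetic_42	11201	.	A	G	.	PASS	DP=162
synthetic_42	11668	.	T	C	.	PASS	DP=164
synthetic_42	11674	.	T	TA	.	PASS	DP=169
synthetic_42	12156	.	A	G	.	PASS	DP=177
synthetic_42	12467	.	A	G	.	PASS	DP=175
synthetic_42	13979	.	T	C	.	PASS	DP=162
synthetic_42	15192	.	C	T	.	PASS	DP=158
synthetic_42	16409	.	T	C	.	PASS	DP=185
synthetic_42	17476	.	A	G	.	PASS	DP=150
synthetic_42	18911	.	T	C	.	PASS	DP=155
synthetic_42	19117	.	C	T	.	PASS	DP=171
synthetic_42	19869	.	T	G	.	PASS	DP=167
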