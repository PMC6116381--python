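##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	3172	.	A	G	.	PASS	DP=156
synthetic_42	4011	.	C	T	.	PASS	DP=177
synthetic_42	4305	.	A	G	.	PASS	DP=167
synthetic_42	5745	.	G	A	.	PASS	DP=179
synthetic_42	6722	.	C	T	.	PASS	DP=154
synthetic_42	7001	.	G	A	.	PASS	DP=161
synthetic_42	7621	.	T	C	.	PASS	DP=166
synthetic_42	10292	.	C	T	.	PASS	DP=157
synthetic_42	11252	.	A	G	.	PASS	DP=153
synthetic_42	11627	.	A	G	.	PASS	DP=161
synthetic_42	12245	.	C	T	.	PASS	DP=157
synthetic_42	12690	.	A	G	.	PASS	DP=163
synthetic_42	13757	.	C	T	.	PASS	DP=181
synthetic_42	14551	.	G	A	.	PASS	DP=151
synthetic_42	15000	.	G	A	.	PASS	DP=185
synthetic_42	15233	.	G	A	.	PASS	DP=165
synthetic_42	16954	.	C	T	.	PASS	DP=163
synthetic_42	17261	.	C	T	.	PASS	DP=159
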