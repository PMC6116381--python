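##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	280	.	C	T	.	PASS	DP=140
synthetic_42	5473	.	A	G	.	PASS	DP=169
synthetic_42	6308	.	C	T	.	PASS	DP=160
synthetic_42	7011	.	AC	A	.	PASS	DP=153
synthetic_42	7097	.	C	CC	.	PASS	DP=182
synthetic_42	8066	.	C	T	.	PASS	DP=141
synthetic_42	8511	.	C	T	.	PASS	DP=141
synthetic_42	9406	.	C	T	.	PASS	DP=160
synthetic_42	9686	.	C	T	.	PASS	DP=178
synthetic_42	10673	.	C	T	.	PASS	DP=178
synthetic_42	10820	.	C	G	.	PASS	DP=158
synthetic_42	12511	.	T	TG	.	PASS	DP=158
synthetic_42	14030	.	C	T	.	PASS	DP=173
synthetic_42	16764	.	G	A	.	PASS	DP=148
synthetic_42	17944	.	T	C	.	PASS	DP=170
synthetic_42	18669	.	C	T	.	PASS	DP=166
synthetic_42	19794	.	G	A	.	PASS	DP=143
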