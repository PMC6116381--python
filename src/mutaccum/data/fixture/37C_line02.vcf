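##fileformat=VCFv4.2
##contig=<ID=synthetic_42,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
synthetic_42	581	.	T	C	.	PASS	DP=161
synthetic_42	616	.	C	T	.	PASS	DP=153
synthetic_42	1530	.	AA	A	.	PASS	DP=158
synthetic_42	2035	.	T	C	.	PASS	DP=148
synthetic_42	2269	.	A	G	.	PASS	DP=163
synthetic_42	2582	.	C	CC	.	PASS	DP=157
synthetic_42	3125	.	T	C	.	PASS	DP=151
synthetic_42	3282	.	T	C	.	PASS	DP=185
synthetic_42	3442	.	A	G	.	PASS	DP=149
synthetic_42	3746	.	G	A	.	PASS	DP=156
synthetic_42	5972	.	A	G	.	PASS	DP=145
synthetic_42	6137	.	C	T	.	PASS	DP=174
synthetic_42	6228	.	TG	T	.	PASS	DP=178
synthetic_42	6667	.	G	A	.	PASS	DP=170
synthetic_42	6841	.	A	G	.	PASS	DP=166
synthetic_42	8791	.	C	T	.	PASS	DP=175
synthetic_42	9541	.	G	A	.	PASS	DP=164
synthetic_42	10220	.	A	G	.	PASS	DP=171
synthetic_42	10684	.	T	C	.	PASS	DP=152
synthetic_42	10720	.	C	T	.	PASS	DP=144
synthetic_42	11309	.	T	C	.	PASS	DP=148
synthetic_42	12235	.	C	G	.	PASS	DP=171
synthetic_42	12279	.	TT	T	.	PASS	DP=163
synthetic_42	12370	.	A	G	.	PASS	DP=158
synthetic_42	12470	.	AAG	A	.	PASS	DP=174
synthetic_42	12479	.	A	AA	.	PASS	DP=162
synthetic_42	13048	.	C	T	.	PASS	DP=151
synthetic_42	13072	.	G	A	.	PASS	DP=169
synthetic_42	13562	.	G	A	.	PASS	DP=205
synthetic_42	13824	.	GTACC	G	.	PASS	DP=150
synthetic_42	14461	.	G	A	.	PASS	DP=146
synthetic_42	14559	.	T	C	.	PASS	DP=177
synthetic_42	15524	.	A	G	.	PASS	DP=178
synthetic_42	16411	.	T	C	.	PASS	DP=127
synthetic_42	17330	.	C	CC	.	PASS	DP=164
synthetic_42	17643	.	G	A	.	PASS	DP=168
synthetic_42	19264	.	C	T	.	PASS	DP=145
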