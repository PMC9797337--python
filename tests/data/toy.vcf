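##fileformat=VCFv4.2
##source=pathburden-test-fixture
##contig=<ID=chr1>
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="Consequence term">
##INFO=<ID=POP_AC,Number=A,Type=Integer,Description="Reference population ALT allele count">
##INFO=<ID=POP_AN,Number=A,Type=Integer,Description="Reference population allele number">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	A	B	C
chr1	1000	r1	C	T	.	PASS	GENE=GENE1;CSQ_CLASS=stop_gained;POP_AC=10;POP_AN=280000	GT	0/1	1/1	0/0
chr1	2000	r2	G	A	.	PASS	GENE=GENE1;CSQ_CLASS=missense_variant;POP_AC=0;POP_AN=280000	GT	0/1	0/0	0/0
chr1	3000	r3	T	C	.	PASS	GENE=GENE2;CSQ_CLASS=stop_gained;POP_AC=11;POP_AN=280000	GT	0/0	0/1	0/1
chr1	4000	r4	A	T,TGG	.	PASS	GENE=GENE3,GENE3;CSQ_CLASS=splice_donor_variant,frameshift_variant;POP_AC=0,5;POP_AN=280000,280000	GT	1/2	0/2	./.
chr1	5000	r5	A	G	.	PASS	GENE=GENE4;CSQ_CLASS=start_lost;POP_AC=2;POP_AN=140000	GT	0/0	0/0	0/1
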