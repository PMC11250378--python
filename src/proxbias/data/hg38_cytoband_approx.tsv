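# Approximate hg38 cytoband summary (synthetic stand-in): exact arm
# topology, coordinates approximate to ~1 Mb. chrom	start	end	band	stain
chr1	0	121700000	p11	gneg
chr1	121700000	123400000	p11.1	acen
chr1	123400000	125100000	q11.1	acen
chr1	125100000	248960000	q11	gneg
chr2	0	91800000	p11	gneg
chr2	91800000	93900000	p11.1	acen
chr2	93900000	96000000	q11.1	acen
chr2	96000000	242190000	q11	gneg
chr3	0	87800000	p11	gneg
chr3	87800000	90900000	p11.1	acen
chr3	90900000	94000000	q11.1	acen
chr3	94000000	198300000	q11	gneg
chr4	0	48200000	p11	gneg
chr4	48200000	50000000	p11.1	acen
chr4	50000000	51800000	q11.1	acen
chr4	51800000	190210000	q11	gneg
chr5	0	46100000	p11	gneg
chr5	46100000	48100000	p11.1	acen
chr5	48100000	50100000	q11.1	acen
chr5	50100000	181540000	q11	gneg
chr6	0	58500000	p11	gneg
chr6	58500000	60550000	p11.1	acen
chr6	60550000	62600000	q11.1	acen
chr6	62600000	170810000	q11	gneg
chr7	0	58100000	p11	gneg
chr7	58100000	60100000	p11.1	acen
chr7	60100000	62100000	q11.1	acen
chr7	62100000	159350000	q11	gneg
chr8	0	43200000	p11	gneg
chr8	43200000	45200000	p11.1	acen
chr8	45200000	47200000	q11.1	acen
chr8	47200000	145140000	q11	gneg
chr9	0	42200000	p11	gneg
chr9	42200000	43850000	p11.1	acen
chr9	43850000	45500000	q11.1	acen
chr9	45500000	138390000	q11	gneg
chr10	0	38800000	p11	gneg
chr10	38800000	40200000	p11.1	acen
chr10	40200000	41600000	q11.1	acen
chr10	41600000	133800000	q11	gneg
chr11	0	51000000	p11	gneg
chr11	51000000	53400000	p11.1	acen
chr11	53400000	55800000	q11.1	acen
chr11	55800000	135090000	q11	gneg
chr12	0	34700000	p11	gneg
chr12	34700000	36450000	p11.1	acen
chr12	36450000	38200000	q11.1	acen
chr12	38200000	133280000	q11	gneg
chr13	0	16000000	p11	gneg
chr13	16000000	17450000	p11.1	acen
chr13	17450000	18900000	q11.1	acen
chr13	18900000	114360000	q11	gneg
chr14	0	16000000	p11	gneg
chr14	16000000	17100000	p11.1	acen
chr14	17100000	18200000	q11.1	acen
chr14	18200000	107040000	q11	gneg
chr15	0	17000000	p11	gneg
chr15	17000000	18750000	p11.1	acen
chr15	18750000	20500000	q11.1	acen
chr15	20500000	101990000	q11	gneg
chr16	0	36300000	p11	gneg
chr16	36300000	37300000	p11.1	acen
chr16	37300000	38300000	q11.1	acen
chr16	38300000	90340000	q11	gneg
chr17	0	22700000	p11	gneg
chr17	22700000	25050000	p11.1	acen
chr17	25050000	27400000	q11.1	acen
chr17	27400000	83260000	q11	gneg
chr18	0	15400000	p11	gneg
chr18	15400000	18200000	p11.1	acen
chr18	18200000	21000000	q11.1	acen
chr18	21000000	80370000	q11	gneg
chr19	0	24400000	p11	gneg
chr19	24400000	26250000	p11.1	acen
chr19	26250000	28100000	q11.1	acen
chr19	28100000	58620000	q11	gneg
chr20	0	25700000	p11	gneg
chr20	25700000	27950000	p11.1	acen
chr20	27950000	30200000	q11.1	acen
chr20	30200000	64440000	q11	gneg
chr21	0	10900000	p11	gneg
chr21	10900000	11950000	p11.1	acen
chr21	11950000	13000000	q11.1	acen
chr21	13000000	46710000	q11	gneg
chr22	0	13700000	p11	gneg
chr22	13700000	15550000	p11.1	acen
chr22	15550000	17400000	q11.1	acen
chr22	17400000	50820000	q11	gneg
chrX	0	58100000	p11	gneg
chrX	58100000	60950000	p11.1	acen
chrX	60950000	63800000	q11.1	acen
chrX	63800000	156040000	q11	gneg
chrY	0	10300000	p11	gneg
chrY	10300000	10450000	p11.1	acen
chrY	10450000	10600000	q11.1	acen
chrY	10600000	57230000	q11	gneg
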