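CHROM	POS	REF	ALT	GENE	TRANSCRIPT	HGVS_C	HGVS_P	CSQ	EXON	INTRON	BDIST	HETAF	HOMAF	GVGD	FMKL	CADD	MT	SIFT	SPLICE_DELTA	PRIOR	GT:1[I:1]	GT:1[II:1]	GT:1[II:3]	GT:1[III:3]	GT:2[I:1]	GT:2[I:2]	GT:2[II:1]	GT:3[I:1]	GT:3[I:2]	GT:3[II:1]	GT:4[I:2]	GT:4[II:2]	GT:4[II:3]	GT:4[III:1]	GT:5[I:1]	GT:5[I:2]	GT:5[II:1]	GT:6[I:1]	GT:6[I:2]	GT:6[II:1]	GT:7[II:1]	GT:8[I:1]	GT:8[I:2]	GT:8[II:1]
8	61734521	A	G	CHD7	NM_017780.3	c.2095A>G	p.Ser699Gly	missense	3	.	2	0%	0%	C0	0.95	15.4	disease_causing	0.2	-0.3	same_variant_comparable_phenotype	.	.	.	.	ref	ref	het	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
4	187630595	CAA	C	FAT1	NM_005245.3	c.5970_5971del	p.Asn1991PhefsTer19	frameshift	10	.	.	0%	0%	.	.	.	.	.	.	none	.	.	.	.	.	.	.	ref	het	hemi	.	.	.	.	.	.	.	.	.	.	.	.	.	.
9	98268722	C	T	PTCH1	NM_000264.4	c.490G>A	p.Glu164Lys	missense	3	.	.	0%	0%	C0	0.92	18.1	disease_causing	0.31	.	none	.	.	.	.	.	.	.	.	.	.	het	het	het	het	.	.	.	.	.	.	.	.	.	.
8	144899115	T	TG	PUF60	NM_001136033.2	c.752dup	p.Gln252ProfsTer152	frameshift	9	.	.	0%	0%	.	.	.	.	.	.	none	.	.	.	.	.	.	.	.	.	.	.	.	.	.	ref	ref	het	.	.	.	.	.	.	.
3	9784577	G	GT	BRPF1	NM_001003694.1	c.1756_1757insT	p.Glu586ValfsTer12	frameshift	5	.	.	0%	0%	.	.	.	.	.	.	none	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	ref	ref	het	.	.	.	.
1	218609733	C	T	TGFB2	NM_001135599.3	c.1043G>A	p.Arg348His	missense	7	.	.	0.00082%	0%	C0	0.98	35	disease_causing	0.0	.	same_residue_different_change	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	het	.	.	.
2	36662850	C	T	CRIM1	NM_016441.2	c.926C>T	p.Pro309Leu	missense	5	.	.	0%	0%	C0	0.9	25	disease_causing	0.4	.	none	het	.	het	het	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
3	9783222	G	A	BRPF1	NM_001003694.1	c.1489G>A	p.Ala497Thr	missense	3	.	.	0%	0%	C0	0.88	25	disease_causing	0.55	.	none	ref	.	ref	het	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
12	114801320	C	A	TBX5	NM_000192.3	c.349G>T	p.Ala117Ser	missense	4	.	.	0%	0%	C0	0.91	24.7	disease_causing	0.2	.	none	.	.	.	.	.	.	.	ref	het	het	.	.	.	.	.	.	.	.	.	.	.	.	.	.
2	202901630	G	A	FZD7	NM_003507.1	c.1154C>T	p.Ala385Val	missense	1	.	.	0.0004%	0%	C0	0.93	32	disease_causing	0.3	.	none	.	.	.	.	.	.	.	ref	het	het	.	.	.	.	.	.	.	.	.	.	.	.	.	.
12	80211510	G	C	PPP1R12A	NM_001143885.1	c.2014C>G	p.Pro672Ala	missense	15	.	.	0%	0%	C0	0.9	24	disease_causing	0.4	.	none	.	.	.	.	.	.	.	.	.	.	ref	het	ref	het	.	.	.	.	.	.	.	.	.	.
17	79477855	C	CT	ACTG1	NM_001199954.1	c.803-18dup	p.?	intronic	.	4	-18	0%	0%	.	.	.	.	.	-0.2	none	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	het	.	.	.
17	42942805	G	C	EFTUD2	NM_001142605.1	c.765-15C>G	p.?	intronic	.	10	-15	0%	0%	.	.	.	.	.	0	none	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	het	ref	het
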