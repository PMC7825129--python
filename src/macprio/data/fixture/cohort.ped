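#FID	IID	FATHER	MOTHER	SEX	AFFECTION	COLOBOMA	MICROPHTHALMIA	EXTRAOCULAR	INDEX	CARRIER	TABLE1
1	1[I:1]	0	0	1	2	1	0	0	0	0	1
1	1[I:2]	0	0	2	1	0	0	0	0	0	0
1	1[II:1]	1[I:1]	1[I:2]	1	0	0	0	0	0	0	0
1	1[II:3]	1[I:1]	1[I:2]	1	2	1	0	0	0	0	1
1	1[II:4]	0	0	2	1	0	0	0	0	0	0
1	1[III:3]	1[II:3]	1[II:4]	2	2	1	0	0	1	0	1
2	2[I:1]	0	0	1	1	0	0	0	0	0	0
2	2[I:2]	0	0	2	1	0	0	0	0	0	0
2	2[II:1]	2[I:1]	2[I:2]	1	2	1	0	1	1	0	1
3	3[I:1]	0	0	1	1	0	0	0	0	0	0
3	3[I:2]	0	0	2	1	0	0	0	0	0	0
3	3[II:1]	3[I:1]	3[I:2]	2	2	1	0	1	1	0	1
4	4[I:1]	0	0	1	1	0	0	0	0	0	0
4	4[I:2]	0	0	2	1	0	0	0	0	1	1
4	4[II:2]	4[I:1]	4[I:2]	2	2	1	0	0	1	0	1
4	4[II:3]	4[I:1]	4[I:2]	2	1	0	0	0	0	1	1
4	4[II:4]	0	0	1	1	0	0	0	0	0	0
4	4[III:1]	4[II:4]	4[II:2]	2	2	1	0	1	0	0	1
5	5[I:1]	0	0	1	1	0	0	0	0	0	0
5	5[I:2]	0	0	2	1	0	0	0	0	0	0
5	5[II:1]	5[I:1]	5[I:2]	2	2	1	1	1	1	0	1
6	6[I:1]	0	0	1	1	0	0	0	0	0	0
6	6[I:2]	0	0	2	1	0	0	0	0	0	0
6	6[II:1]	6[I:1]	6[I:2]	1	2	1	1	0	1	0	1
7	7[II:1]	0	0	2	2	1	1	0	1	0	1
8	8[I:1]	0	0	1	1	0	0	0	0	0	0
8	8[I:2]	0	0	2	1	0	0	0	0	0	0
8	8[II:1]	8[I:1]	8[I:2]	2	2	1	0	1	1	0	1
9	9[II:1]	0	0	1	1	0	0	0	0	0	0
9	9[II:2]	0	0	2	2	1	1	0	1	0	1
9	9[III:1]	9[II:1]	9[II:2]	1	2	1	1	0	0	0	1
10	10[II:1]	0	0	2	2	1	1	0	1	0	1
11	11[II:2]	0	0	2	2	1	0	0	1	0	1
12	12[II:2]	0	0	2	2	1	0	0	1	0	1
13	13[IV:4]	0	0	2	2	1	1	1	1	0	1
14	14[II:1]	0	0	1	2	1	0	0	1	0	1
15	15[II:1]	0	0	2	2	1	0	0	1	0	1
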