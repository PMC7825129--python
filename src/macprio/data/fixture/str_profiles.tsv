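individual	marker	allele1	allele2
2[I:1]	M01	12	13
2[I:1]	M02	14	15
2[I:1]	M03	13	16
2[I:1]	M04	11	13
2[I:1]	M05	15	16
2[I:1]	M06	10	16
2[I:1]	M07	11	17
2[I:1]	M08	10	11
2[I:1]	M09	9	13
2[I:1]	M10	10	15
2[I:1]	M11	13	16
2[I:1]	M12	8	13
2[I:1]	M13	12	15
2[I:1]	M14	12	12
2[I:1]	M15	14	17
2[I:1]	M16	11	13
2[I:1]	M17	9	10
2[I:1]	M18	10	17
2[I:1]	M19	8	11
2[I:1]	M20	15	17
2[I:1]	M21	10	15
2[I:1]	M22	8	9
2[I:1]	M23	11	17
2[I:1]	M24	9	17
2[I:2]	M01	14	16
2[I:2]	M02	12	12
2[I:2]	M03	11	12
2[I:2]	M04	8	16
2[I:2]	M05	13	15
2[I:2]	M06	11	13
2[I:2]	M07	12	17
2[I:2]	M08	16	17
2[I:2]	M09	9	13
2[I:2]	M10	14	17
2[I:2]	M11	13	17
2[I:2]	M12	8	17
2[I:2]	M13	8	15
2[I:2]	M14	8	17
2[I:2]	M15	16	17
2[I:2]	M16	11	12
2[I:2]	M17	14	15
2[I:2]	M18	16	17
2[I:2]	M19	10	11
2[I:2]	M20	14	17
2[I:2]	M21	8	11
2[I:2]	M22	11	17
2[I:2]	M23	12	14
2[I:2]	M24	8	16
2[II:1]	M01	13	14
2[II:1]	M02	12	14
2[II:1]	M03	12	16
2[II:1]	M04	8	13
2[II:1]	M05	15	15
2[II:1]	M06	11	16
2[II:1]	M07	11	17
2[II:1]	M08	11	17
2[II:1]	M09	9	13
2[II:1]	M10	10	14
2[II:1]	M11	16	17
2[II:1]	M12	13	17
2[II:1]	M13	12	15
2[II:1]	M14	8	12
2[II:1]	M15	17	17
2[II:1]	M16	12	13
2[II:1]	M17	9	14
2[II:1]	M18	10	16
2[II:1]	M19	10	11
2[II:1]	M20	15	17
2[II:1]	M21	8	15
2[II:1]	M22	9	11
2[II:1]	M23	12	17
2[II:1]	M24	8	9
5[I:1]	M01	9	13
5[I:1]	M02	10	13
5[I:1]	M03	11	12
5[I:1]	M04	10	15
5[I:1]	M05	10	13
5[I:1]	M06	9	12
5[I:1]	M07	9	11
5[I:1]	M08	12	15
5[I:1]	M09	8	9
5[I:1]	M10	8	16
5[I:1]	M11	11	15
5[I:1]	M12	13	15
5[I:1]	M13	12	17
5[I:1]	M14	8	10
5[I:1]	M15	9	17
5[I:1]	M16	10	13
5[I:1]	M17	10	13
5[I:1]	M18	8	12
5[I:1]	M19	10	14
5[I:1]	M20	10	16
5[I:1]	M21	14	15
5[I:1]	M22	14	16
5[I:1]	M23	12	14
5[I:1]	M24	11	15
5[I:2]	M01	11	16
5[I:2]	M02	15	15
5[I:2]	M03	9	14
5[I:2]	M04	13	15
5[I:2]	M05	15	17
5[I:2]	M06	15	16
5[I:2]	M07	16	17
5[I:2]	M08	8	17
5[I:2]	M09	8	16
5[I:2]	M10	10	14
5[I:2]	M11	8	16
5[I:2]	M12	10	10
5[I:2]	M13	11	12
5[I:2]	M14	9	10
5[I:2]	M15	8	12
5[I:2]	M16	8	11
5[I:2]	M17	16	17
5[I:2]	M18	10	15
5[I:2]	M19	10	11
5[I:2]	M20	15	16
5[I:2]	M21	14	16
5[I:2]	M22	8	14
5[I:2]	M23	9	12
5[I:2]	M24	10	10
5[II:1]	M01	9	11
5[II:1]	M02	13	15
5[II:1]	M03	12	14
5[II:1]	M04	10	13
5[II:1]	M05	13	15
5[II:1]	M06	12	15
5[II:1]	M07	9	17
5[II:1]	M08	8	15
5[II:1]	M09	8	9
5[II:1]	M10	8	10
5[II:1]	M11	15	16
5[II:1]	M12	10	15
5[II:1]	M13	11	17
5[II:1]	M14	8	9
5[II:1]	M15	9	12
5[II:1]	M16	8	13
5[II:1]	M17	10	16
5[II:1]	M18	8	10
5[II:1]	M19	10	14
5[II:1]	M20	10	15
5[II:1]	M21	14	16
5[II:1]	M22	8	16
5[II:1]	M23	9	12
5[II:1]	M24	10	15
6[I:1]	M01	14	15
6[I:1]	M02	8	12
6[I:1]	M03	8	13
6[I:1]	M04	9	14
6[I:1]	M05	9	11
6[I:1]	M06	10	17
6[I:1]	M07	10	10
6[I:1]	M08	13	16
6[I:1]	M09	13	17
6[I:1]	M10	9	16
6[I:1]	M11	13	17
6[I:1]	M12	10	10
6[I:1]	M13	8	8
6[I:1]	M14	14	16
6[I:1]	M15	10	12
6[I:1]	M16	9	11
6[I:1]	M17	10	11
6[I:1]	M18	12	17
6[I:1]	M19	13	17
6[I:1]	M20	8	16
6[I:1]	M21	17	17
6[I:1]	M22	8	14
6[I:1]	M23	16	16
6[I:1]	M24	11	15
6[I:2]	M01	10	17
6[I:2]	M02	9	13
6[I:2]	M03	12	14
6[I:2]	M04	13	15
6[I:2]	M05	12	14
6[I:2]	M06	10	12
6[I:2]	M07	12	15
6[I:2]	M08	15	17
6[I:2]	M09	11	13
6[I:2]	M10	8	15
6[I:2]	M11	8	16
6[I:2]	M12	13	15
6[I:2]	M13	15	16
6[I:2]	M14	9	11
6[I:2]	M15	11	14
6[I:2]	M16	10	13
6[I:2]	M17	9	10
6[I:2]	M18	9	11
6[I:2]	M19	10	15
6[I:2]	M20	10	14
6[I:2]	M21	12	14
6[I:2]	M22	10	12
6[I:2]	M23	14	17
6[I:2]	M24	13	14
6[II:1]	M01	10	14
6[II:1]	M02	8	13
6[II:1]	M03	12	13
6[II:1]	M04	14	15
6[II:1]	M05	11	12
6[II:1]	M06	10	12
6[II:1]	M07	10	12
6[II:1]	M08	16	17
6[II:1]	M09	13	17
6[II:1]	M10	15	16
6[II:1]	M11	13	16
6[II:1]	M12	10	13
6[II:1]	M13	8	16
6[II:1]	M14	9	14
6[II:1]	M15	10	14
6[II:1]	M16	9	10
6[II:1]	M17	10	11
6[II:1]	M18	9	12
6[II:1]	M19	15	17
6[II:1]	M20	8	14
6[II:1]	M21	12	17
6[II:1]	M22	8	12
6[II:1]	M23	16	17
6[II:1]	M24	11	14
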