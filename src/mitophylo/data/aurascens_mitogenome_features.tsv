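# Annotation and per-gene base composition of the Myotis aurascens mitogenome
# (GenBank OK053029), sequence-free mode: composition columns are percentages
# of A/C/G/T as published with the genome organization table.
#identifier=OK053029
#circular=true
#length=16771
#total_pct_a=33.93
#total_pct_c=22.17
#total_pct_g=12.96
#total_pct_t=30.94
name	class	strand	start	end	start_codon	stop_codon	pct_a	pct_c	pct_g	pct_t
tRNA-Phe	tRNA	H	1	68	-	-	36.76	22.06	16.18	25.00
12S-rRNA	rRNA	H	69	1034	-	-	36.96	21.22	17.49	24.33
tRNA-Val	tRNA	H	1035	1103	-	-	39.13	17.39	13.04	30.43
16S-rRNA	rRNA	H	1103	2670	-	-	38.90	18.56	15.68	25.96
tRNA-Leu2	tRNA	H	2672	2746	-	-	30.67	18.67	21.33	29.33
ND1	PCG	H	2752	3707	ATG	TA-	32.74	23.85	11.09	32.32
tRNA-Ile	tRNA	H	3708	3776	-	-	34.78	11.59	17.39	36.23
tRNA-Gln	tRNA	L	3774	3847	-	-	29.73	10.81	24.32	35.14
tRNA-Met	tRNA	H	3848	3916	-	-	28.99	24.64	18.84	27.54
ND2	PCG	H	3917	4958	ATT	T--	39.25	25.24	7.58	27.93
tRNA-Trp	tRNA	H	4959	5026	-	-	33.82	22.06	16.18	27.94
tRNA-Ala	tRNA	L	5032	5100	-	-	28.99	11.59	21.74	37.68
tRNA-Asn	tRNA	L	5102	5174	-	-	24.66	13.70	21.92	39.73
tRNA-Cys	tRNA	L	5207	5272	-	-	27.27	21.21	24.24	27.27
tRNA-Tyr	tRNA	L	5273	5341	-	-	36.23	17.39	20.29	26.09
COX1	PCG	H	5343	6887	ATG	TAA	27.06	20.65	16.89	35.40
tRNA-Ser2	tRNA	L	6901	6969	-	-	24.64	15.94	24.64	34.78
tRNA-Asp	tRNA	H	6977	7043	-	-	37.31	11.94	13.43	37.31
COX2	PCG	H	7044	7727	ATG	TAA	33.92	21.93	12.57	31.58
tRNA-Lys	tRNA	H	7731	7798	-	-	35.29	19.12	14.71	30.88
ATP8	PCG	H	7799	8002	ATG	TAA	40.22	22.55	6.86	30.39
ATP6	PCG	H	7960	8640	ATG	TAA	32.60	23.05	11.60	32.75
COX3	PCG	H	8640	9423	ATG	T--	28.57	22.70	14.16	34.57
tRNA-Gly	tRNA	H	9424	9493	-	-	37.14	17.14	14.29	31.43
ND3	PCG	H	9494	9840	ATA	TA-	30.84	20.17	11.24	37.75
tRNA-Arg	tRNA	H	9841	9909	-	-	42.03	8.70	8.70	40.58
ND4L	PCG	H	9911	10207	ATG	TAA	28.28	22.56	12.12	37.04
ND4	PCG	H	10201	11579	ATG	TA-	33.14	23.42	10.51	32.92
tRNA-His	tRNA	H	11580	11647	-	-	45.59	8.82	10.29	35.29
tRNA-Ser1	tRNA	H	11647	11705	-	-	33.90	20.34	16.95	28.81
tRNA-Leu1	tRNA	H	11706	11775	-	-	38.57	14.29	20.00	27.14
ND5	PCG	H	11777	13597	ATA	TAA	33.44	22.73	10.16	33.66
ND6	PCG	L	13581	14105	ATA	TAA	24.19	6.67	25.71	43.43
tRNA-Glu	tRNA	L	14108	14176	-	-	28.99	14.49	21.74	34.78
Cytb	PCG	H	14184	15323	ATG	AGA	29.82	23.95	13.07	33.16
tRNA-Thr	tRNA	H	15324	15393	-	-	37.14	14.29	18.57	30.00
tRNA-Pro	tRNA	L	15393	15458	-	-	24.24	10.61	27.27	37.88
D-loop	control_region	H	15459	16771	-	-	34.96	23.76	14.09	27.19
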