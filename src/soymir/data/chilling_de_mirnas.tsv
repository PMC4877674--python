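mirna	sequence	norm_control	norm_chilling	log2_reported
gma-miR156r	CTGACAGAAGATAGAGAGCAT	2580.30	127.89	-4.33
gma-miR5761a	TTTTGTGTCGTGAAGCTTTTG	71.43	5.12	-3.80
gma-MIR5032-p3	AACGGAGCCACTGTGAAGAAGT	10.74	0.93	-3.53
gma-miR159d	AGCTGCTTAGCTATGGATCCC	24.35	2.48	-3.29
gma-miR172-5p	GTAGCATCATCAAGATTCACA	86.38	13.03	-2.73
gma-MIR171e-p5	TGTTGGACGGTTCAATCAAA	11.82	1.86	-2.67
gma-MIR4413a-p3	ATACAGTGACTTACAATTCTC	40.82	6.52	-2.65
gma-MIR319i-p5	AGGAGCTTCCTTCAGCCCATG	10.74	1.86	-2.53
gma-MIR5372-p3	ATAATGTACAACACAATTATC	174.02	37.24	-2.22
gma-MIR159d-p3	CTTCCATATCTGGGGAGCTTC	156.65	33.82	-2.21
gma-miR4413b	TAAGAGAATTGTAAGTCA	70.36	15.83	-2.15
gma-miR172c	AGAATCTTGATGATGCTGCAN	66.96	16.29	-2.04
gma-miR5674a	TAATTGTGTTGTACATTATCA	52.10	13.03	-2.00
gma-MIR1508a	ACTGCTATTCCCATTTCTAAA	222.35	58.65	-1.92
gma-MIR167g	GATCATGTGGCTGCTTCACC	371.66	101.47	-1.87
gma-MIR167f	AGATCATGTGGCAGTTTCACC	23.63	6.52	-1.86
gma-MIR4416c	ACGGGTCGCTCTCACCTGGAG	2016.22	572.53	-1.82
gma-miR156a	TGACAGAAGAGAGTGAGCAC	11137.16	3193.80	-1.80
gma-miR394a-3p	AGCTCTGTTGGCTACACTTTG	30.08	9.31	-1.69
gma-MIR4412	GGCGTAGATCCCCACAACAGT	18.26	6.52	-1.49
gma-miR4413a	TAAGAGAATTGTAAGTCACTG	2328.27	838.79	-1.47
gma-miR172h-5p	GCAGCAGCATCAAGATTCACA	167.03	62.37	-1.42
gma-MIR1535a-p5	AGACATCACCACAAACAAGTC	20.41	8.38	-1.28
gma-miR393a	TTCCAAAGGGATCGCATTGATC	31.92	13.13	-1.28
gma-miR5667	AAACAGATCTAAATGGATTCC	70.90	29.79	-1.25
gma-miR397b-3p	TATTGACGCTGCACTCAATCA	2641.39	1150.65	-1.20
gma-MIR5374-p3	TTCGAATGTCAGATTATAAAA	29.00	13.03	-1.15
gma-miR162a	TCGATAAACCTCTGCATCCAG	173.48	80.06	-1.12
gma-miR5767	TGGAGGACCTTTGAAGGTGCA	1116.07	524.12	-1.09
gma-miR171n	TTGAGCCGCGTCAATATCTTA	41.36	20.25	-1.03
gma-miR1535a	CTTGTTTGTGGTGATGTCTAG	133.73	272.30	1.03
gma-MIR166r-p5	GGAATGCAGTGTGGTCCAAGG	42.97	90.30	1.07
gma-miR1507a	TCTCATTCCATACATCGTCTGA	11988.30	26404.05	1.14
gma-MIR1511-p5	GTGGTATCAGGTCCTGCTTCA	56.93	126.61	1.15
gma-MIR1520k-p3	TTGACATCCAATCAGAACATGACA	70.18	162.53	1.21
gma-miR4376-5p	TACGCAGGAGAGATGACGCTG	962.46	2311.55	1.26
gma-miR4411	TTATTGTAACTAATTTGTCGGT	15.04	42.82	1.51
gma-miR4382	TATGTTAACTGATTTCATGGAT	10.74	34.45	1.68
gma-MIR166e-p5	GGAATGTTGGCTGGCTCGAGG	42.03	158.78	1.92
gma-miR164a	TGGAGAAGCAGGGCACGTGCA	627.16	2452.21	1.97
gma-miR171b-3p	CGAGCCGAATCAATATCACTC	6.71	27.00	2.01
gma-miR4416b	TGGGTGAGAGAAACGCGTATC	75.73	313.11	2.05
gma-miR5559	TACTTGGTGAATTGTTGGATC	11.82	52.13	2.14
gma-miR169e	TGAGCCAAGGATGACTTGCCG	4.19	20.37	2.28
gma-miR169c	AAGCCAAGGATGACTTGCCGA	3.76	21.96	2.55
gma-MIR169a-p3	GGCAAGTTGTGTTTGGCTAT	2.15	14.90	2.79
gma-MIR171b-p5	CGTGATATTGGTACGGCTCATC	3.22	26.07	3.02
gma-MIR156l-p3	GCTCTCTAAGCTTCTGTCATCC	4.30	37.24	3.12
gma-MIR156m-p3	GCTCTCTAGGCTTCTGTCATCC	3.22	28.86	3.16
gma-miR169l-3p	CGGGCAAGTTGTTTTTGGCTAC	1.07	16.29	3.92
gma-miR169d	TGAGCCAAGGATGACTTGCCG	0.97	17.42	4.16
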