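id	sequence	description
P1	AGCTCACTCAAAGGCGGTAA	pUC19_fwd_shorterbackbone2
P2	TCACCGTCATCACCGAAACG	pUC19_rev_shorterbackbone2
P3	CGTTTCGGTGATGACGGTGAACCAAAGGAGCGGAAACC	7036-asRNA1_fwd
P4	TTACCGCCTTTGAGTGAGCTCCTAAACAGAAGGGTTTTTGC	7036-asRNA1_rev
P5	TTACCGCCTTTGAGTGAGCTCTTATAGCTCATATCCAAAACCCAG	7036-asRNA1-7037_rev
P6	TTAGAAAAACTCATCGAGCATCAAATG	pUC19_3637-Km_bb_fwd
P7	CGTTTCGGTGATGACGGTGAGAAGGGATAGCAAGCTAATTTTTATG	pUC19_pPetE_fwd
P8	CTTTGCTCATACTTCTTGGCGATTGTATC	Ppet_GFP_rev
P9	GCCAAGAAGTATGAGCAAAGGAGAAGAAC	Ppet_GFP_fwd
P10	TGCTCGATGAGTTTTTCTAATTTGTAGAGCTCATCCATG	Km_GFP_rev
P11	AGGGAGGCTGATATTGCTCTG	7037_STOP_fwd
P12	GTTCAAGGTGACGGTATTG	7037_STOP_rev
P13	ATGGATTATAAAGATCATGATGG	pUC19_Rha_3xFLAG_fwd
P14	TTCTACCTCCTTTGTATATTATAAAC	pUC19_Rha_3xFLAG_rev
P15	GGAGGTAGAAATGGAAACAGGGCACTCCATCG	7036_F2_Fwd
P16	CTTTATAATCAGCGGCACCCCCTGCAAA	7036_F2_Rev
P17	GCCGACGAAGCCCGGCAGGTAAGACCCCCGCACCGAAA	RP-ilvBN_Fw
P18	CCTGCTGGGTCTGGCTCATGAATAAAAAACGCCCGGCGGCAACCGAGCGAATTATTGCAGAAAGCCATCCC	RhaS_oop_RP_Rev
P19	AATATACAAAGGAGGTAGAAATGAGCAAAGGAGAAGAAC	PRha_sfGFP_fwd
P20	TCATGATCTTTATAATCCATTTTGTAGAGCTCATCCATG	PRha_sfGFP_rev
P21	GGTAGAAATGTAAACAGGGCAC	PRha-7036-Stop_F
P22	TCCTTTGTATATTATAAACTTACC	PRha-7036-Stop_R
P23	GCCGCCCGCATTGGAGAAATAAGACCCCCGCACCGAAA	Rp_XmnI_Prha_fwd
P24	CAGATCGTTGACGAGTATTAAATAAAAAACGCCCGGCGGCAACCG	Rp_XmnI_Prha_rev
P25	GGAAATTGCAATCTTATTCCCATTGACCC	slr7037us1000-f
P26	GGATTTATTTATTCTTACTCCACCCCCCCTGCATCA	7037us-cat-r2
P27	CAGGGCGGGGCGTAAACCTGAGTTAAACAATGGGCACC	cat-7037ds-f5
P28	CTCAATTCTAATCCCAAGCCCCCTCAG	slr7037ds1000-r
P29	CAGGGGGGGTGGAGTAAGAATAAATAAATCCTGGTG	7037us-cat-f3
P30	ATTGTTTAACTCAGGTTTACGCCCCGCCCTGCCACT	cat-7037ds-r4
P31	GCAAAATTTGCAGGGGGTGCCGCTTG	slr7037us200-f
P32	GCCATTCTTTTCCTCCATCACTGCGGTGG	slr7037ds200-r
P33	GAAGACTATCCAAATCGCCAAGG	7036+UTR_Fwd
P34	TAATACGACTCACTATAGGGCTTAGGAACCCCTTCTGTGC	7036+UTR_T7_Rev
P35	TAATACGACTCACTATAGGGCTAAAACCAAAGAAACCCCTC	asRNA1_T7_Fwd
P36	AGATATCAAGCGGCACCC	asRNA1_Rev
P37	CTTTAGGTGGGCGTTGACCT	antiC3S1_fwd
P38	TAATACGACTCACTATAGGGTAATAGTAATGACAGGCAG	antiC3S1_T7_rev
P39	TGGGTTCATTCAATCGACG	cmpA_fw
P40	TAATACGACTCACTATAGGGTGACGTTATCTCTAGCGGAG	cmpA_T7_rv
P41	TAATACGACTCACTATAGGGAAGACTATCCAAATCGCCAAGG	7036_InvTr_T7_Fwd
P42	TAAGACCTTAGGAACCCCTTC	7036_InvTr_Rev
P43	CACCTAAAACCAAAGAAACCCCTC	asRNA1_InvTr_Fwd
P44	TAATACGACTCACTATAGGGTCAAGCGGCACCCCCTGC	asRNA1_InvTr_T7_Rev
P45	CCACAATTCCAGAGGATAGCC	Primer a, genome-structure PCR
P46	GGGTAACTACGACCTACTCC	Primer b, genome-structure PCR
P47	CTGCATCAATGGCGATCGCCGACGGG	Primer c, genome-structure PCR
P48	TGACATGCTGAACCTGCTTGTAAAATGAG	Primer d, genome-structure PCR
P49	GTCGGCCCTATCTTGTTTCCGTAGC	Primer e, genome-structure PCR
P50	CATCAAGCCTCACAAGAGGGAGTATCC	Primer f, genome-structure PCR
P51	GGCAGTGATAGTACCCTGATCACCAT	Primer g, genome-structure PCR
P52	CACAGAACCAGACCATGGAGTGCAA	Primer h, genome-structure PCR
P53	AGTTGACGAAGTAGTTGTGC	Primer m, genome-structure PCR
P54	GAAATGGTGGCAGTGCAGG	Primer n, genome-structure PCR
P55	TCAAATGTTGTTCAAGGGGAAGCTGCATA	Primer o, genome-structure PCR
P56	CACCGACCACCACCGTAAGGCAGGGC	Primer p, genome-structure PCR
P57	GAAATGTTGAATACTCATACTCTTCC	Colony PCR
P58	GTATTACTGTTTATGTAAGCAGACAG	Colony PCR
P59	ATGGTTACTCACCACTGCGATCC	Colony PCR
P60	AGACGAAAGGGCCTCGTG	Colony PCR
P61	AAGTGCCACCTGACGTCTAAG	Colony PCR
P62	CGCTGTCACATTTCACAACCGAGTG	5S hybridization
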