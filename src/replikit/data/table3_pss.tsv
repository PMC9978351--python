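position	strand	tu	comment	fc_wt_ts	padj_wt_ts	fc_wt_5p	padj_wt_5p
32181	+	TU7029	4 nt downstream of TSS of TU7029	-2.40	0.00	-2.13	0.11
32250	+	TU7029	smaller peak in TU7029	1.13	0.14	-1.34	0.09
32251	+	TU7029	smaller peak in TU7029	0.87	0.41	-2.17	0.01
32260	+	TU7029	showing up in rne(5p) data set	2.06	0.52	-3.56	0.03
32284	+	TU7030	defines TU border; 5 nt upstream of ssr7036 start codon, major peak	5.85	0.00	2.09	0.04
32285	+	TU7030	4 nt upstream of ssr7036 start codon	4.28	0.00	-0.12	0.94
32293	+	TU7030	4 nt into ssr7036 CDS	3.62	0.14	0.91	NA
32294	+	TU7030	5 nt into ssr7036 CDS	5.72	0.01	0.68	0.82
32469	+	TU7030	small peak	1.33	0.42	-1.56	NA
32472	+	TU7030	small peak	-1.61	0.07	-0.40	NA
32464	-	TU7031	big peak in asRNA1	-1.06	0.18	0.00	NA
32463	-	TU7031	big peak in asRNA1	-1.02	0.03	1.35	NA
32426	-	TU7031	smaller peak, absent in rne(Ts)	3.97	0.02	3.70	NA
32418	-	TU7031	big peak absent in rne(Ts)	4.16	0.00	-0.59	NA
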