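name	value	strand	note
ssr7036_tss	32177	+	single TSS of the ssr7036 precursor (TU7029)
asrna1_tss	32481	-	single TSS of asRNA1 (TU7031); first nt complementary to the T of the ssr7036 TGA stop
asrna1_three_prime	32329	-	3'-most templated nt of the 153-nt asRNA1
asrna1_substrate_five_prime	32483	-	5'-most templated nt of the in vitro substrate (two nt upstream of the TSS included)
ssr7036_orf_start	32289	+	first nt of the ssr7036 reading frame
ssr7036_orf_end	32483	+	last nt of the reading frame, inclusive of the stop codon
invitro_cut_upstream	32426	-	RNase E cleavage site; 5' nt of the downstream product
invitro_cut_downstream	32418	-	RNase E cleavage site; 5' nt of the downstream product
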