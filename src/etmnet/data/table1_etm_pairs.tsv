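mirna_id	mirna_seq	lncrna_id	etm_site_seq_with_gaps
Novel86	AUCUGGAUCCAAGACUUAAGUGGG	lch-lnc5923	CUCGCUUAAGUCUUAUAUCCAGAA
Novel413	AUCCGACUUAGAUCCAAAAGGUGA	lch-lnc5375	AUACCUUUUGGAUCUGAGUCGGAU
Novel413	AUCCGACUUAGAUCCAAAAGGUGA	lch-lnc1212	UCACCUUUUGGAUCUGAGUCGGAU
Novel325	CAUUCAAUCUGUACUGUGUGGUCC	lch-lnc2550	GGUCCACACAGUAGGGAUUGAAUG
Novel324	UGUGGACUCCGCAUUUGAUGUGUC	lch-lnc5809	GACACAUCAAAUGUGGAGUCCACG
Novel324	UGUGGACUCCGCAUUUGAUGUGUC	lch-lnc5002	GACACAUCAAAUGUGGAGUCCACG
Novel286	UUUCGUGAUGUUUGGUGCAAC	lch-lnc6425	GUUGCACCAAAAAUCACGAAA
Novel286	UUUCGUGAUGUUUGGUGCAAC	lch-lnc4268	GUUGCACCAAAUAUCACGAAA
Novel239	AUGGACUGGCCUGAUUUUUAAGCC	lch-lnc7276	GGCCCAAAAAUCAGG-CAGUCCAA
Novel239	AUGGACUGGCCUGAUUUUUAAGCC	lch-lnc6909	UCCCUAAAAAUCAAUCCAGUCCAU
Novel239	AUGGACUGGCCUGAUUUUUAAGCC	lch-lnc3000	GGCCCAAAAAUCAGGUCAGUCCAU
Novel239	AUGGACUGGCCUGAUUUUUAAGCC	lch-lnc2012	GGUUCAAAAAUCAGCUCAGUCCAU
Novel206	AUCUGUCUGAUUUUUGUGAACGUG	lch-lnc5872	AAGGUUCACAAAA---AGACAGAA
Novel132	CAUUUAUGUAGAGGAAAGCGU	lch-lnc5205	GCGCUUUCCUCUGCAUAAAUG
Novel132	CAUUUAUGUAGAGGAAAGCGU	lch-lnc3557	GCGCUUUCCUCCACAUAAAUG
Novel132	CAUUUAUGUAGAGGAAAGCGU	lch-lnc3556	GCGCUUUCCUCCACAUAAAUG
lch-miR5658	AUGAUGAUGAUGAUGAUGAAA	lch-lnc7426	CAUCAUCAUCACCAUCAUCAC
lch-miR5658	AUGAUGAUGAUGAUGAUGAAA	lch-lnc6738	GGUCAUCAUCAAUAUCAUCAC
lch-miR5658	AUGAUGAUGAUGAUGAUGAAA	lch-lnc6060	AAUCAUCAUCAACAUCAUCAU
lch-miR396a-3p	GUUCAAUAAAGCUGUGGGAAG	lch-lnc5634	CGUCCCACAGUCACAUAUUGAAG
lch-miR157a-3p	GCUCUCUAGCCUUCUGUCAUC	lch-lnc4803	GAUGACAGAAGCAUAGAGAG-
lch-miR156j	UGACAGAAGAGAGAGAGCAC	lch-lnc7374	GUGCUCUCUAUCUUCUGUCA
lch-miR156h	UGACAGAAGAAAGAGAGCAC	lch-lnc7374	GUGCUCUCUAUCUUCUGUCA
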