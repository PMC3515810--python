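species	gene	direction	sequence
mouse	Per1	For	CTTCTGGCAATGGCAAGGACTC
mouse	Per1	Rev	CAGCATCATGCCATCATACACACA
mouse	Tgm2	For	TGTCACCAGGGATGAGAGACGG
mouse	Tgm2	Rev	TCCAAATCACACCTCTCCAGGAG
mouse	Lcn2	For	ACCTCTCATTTCTTGCAGTTCCG
mouse	Lcn2	Rev	CAGGATGGAGGTGACATTGTAGCT
mouse	Actb	For	AGTGTGACGTTGACATCCGTA
mouse	Actb	Rev	GCCAGAGCAGTAATCTCCTTCT
human	NKX3-1	For	TGACAGTGGGCTGTTTGTTC
human	NKX3-1	Rev	AAGACCCCAAGTGCCTTTCT
human	RHOU	For	TTTCAAGGATGCTGGCTCTT
human	RHOU	Rev	GGCCTCAGCTTGTCAAATTC
human	GAPDH	For	AAGGTGAAGGTCGGAGTCAAC
human	GAPDH	Rev	GGGGTCATTGATGGCAACAATA
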