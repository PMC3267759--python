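miRNA	Sequence	Frequency	Species
miR-1	UGGAAUGUAAAGAAGUAUGUAU	1850549	mmu hsa dre
miR-125b	UCCCUGAGACCCUAACUUGUGA	6170	mmu
miR-133a-3p	UUGGUCCCCUUCAACCAGCUGU	1506	mmu dre
miR-155	UUAAUGCUAAUCGUGAUAGGGG	109	mmu
miR-181a-5p	AACAUUCAACGCUGUCGGUGA	14161	mmu
miR-206	UGGAAUGUAAGGAAGUGUGUGG	7555941	mmu hsa
miR-21	UAGCUUAUCAGACUGGUGUUGGC	2082419	rno
miR-214	UACAGCAGGCACAGACAGG	267	mmu dre
miR-221	AGCUACAUUGUCUGCUGGG	26	mmu
miR-222	AGCUACAUCUGGCUACUGGG	45	mmu
miR-23a	AUCACAUUGCCAGGGAUUUCC	130	hsa
miR-24	UGGCUCAGUUCAGCAGGAACAG	3027	mmu
miR-26a	UUCAAGUAAUCCAGGAUAGGCU	8278	mmu
miR-27a	UUCACAGUGGCUAAGUUCCGC	558	mmu
miR-27b	UUCACAGUGGCUAAGUUCUGC	2814	mmu
miR-29b	UAGCACCAUUUGAAAUCAGUGUU	129	mmu hsa
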