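miRNA	Sequence	Frequency	Conserved
cca-let-7h	UGAGGUAGUAAGUUGUGUUGU	159	dre fru tni hno hmo
cca-miR-10d	UACCCUGUAGAACCGAAUGUGU	10	dre fru tni ola hno hmo
cca-miR-27e	UUCACAGUGGCUAAGUUCAGU	126	dre fru tni hno hmo
cca-miR-153b	UUGCAUAGUCACAAAAAUGAGC	6	dre fru tni hno hmo
cca-miR-460-3p	CACAGCGCAUACAAUGUGGAUG	7	dre fru tni ola
cca-miR-142b-5p	CAUAAAGUAGACAGCACUACU	8	dre fru tni hno hmo
cca-miR-430	UAAGUGCUAUUUGUUGGGGUAG	2	dre ola hno hmo
cca-miR-125c	UCCCUGAGACCCUAACUCGUGA	7625	dre ola hno hmo
cca-miR-18c	UAAGGUGCAUCUUGUGUAGUUAG	64	dre hno hmo
cca-miR-19d	UGUGCAAACCCAUGCAAAACUGA	59	dre ola hno hmo
cca-miR-27d	UUCACAGUGGCUAAGUUCUUC	22	dre ola hno hmo
cca-miR-454b	UAGUGCAAUAUUGCUUAUAGG	36	dre hno hmo
cca-miR-462	UAACGGAACCCAUAAUGCAGCUG	1518	dre ola hno hmo
cca-miR-722	UUUUUUGCAGAAACGUUUCAG	53	dre hno hmo
cca-miR-724	UUAAAGGGAAUUUGCGACUGUU	65	dre hno hmo
cca-miR-725	UUCAGUCAUUGUUUCUAGUAGU	58	dre hno hmo
cca-miR-726	UUCACUACUAGCAGAACUCGG	19	dre
cca-miR-730	UCCUCAUUGUGCAUGCUGUGUG	154	dre
cca-miR-731	AAUGACACGUUUUCUCCCGGAUC	97	dre ola hno hmo
cca-miR-135c	UAUGGCUUUCUAUUCCUAUGUGA	7	dre hno hmo
cca-miR-153c	UUGCAUAGUCACAAAAAUGAUC	2	dre hno hmo
cca-miR-734	UAAAUGCUGCAGAAUCGUACCG	7	dre hno hmo
cca-miR-18b	UAAGGUGCAUUUAGUGCAGAUAG	3	dre
cca-miR-457a	AGCAGCACAUCAAUAUUGGC	4	dre hno hmo
cca-miR-457b	AGCAGCACAUAAAUACUGGAG	1	dre hno hmo
cca-miR-459-5p	AGUAACAAGGAUUCAUCCUGUU	4	dre ola
cca-miR-727-3p	GUUGAGGCGAGUUGAAGACUUA	4	dre hno hmo
cca-miR-729	CAUGGGUAUGAUACGACCUGGG	1	dre
cca-miR-738	GCUACGGCCCGCGUCGGGA	1	dre
cca-miR-27c-5p	CAGGACUUAACCCACUUGUGAAC	310	dre
cca-miR-459-3p	CAGGGAAUCUCUGUUACUGGG	4	dre ola
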