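miRNA	Sequence	Frequency
CM1-m0001_3p	UGGAAGUGAAUGGUGACUGAG	12
CM1-m0002_3p	GCGACCCAUCCUUGGUUUCUG	12
CM1-m0003_5p	ACCAUGGCUGUAGACUGUUACC	42
CM1-m0004_3p	UCAAGGUCCGCUGUGAACACGA	8
CM1-m0005_3p	UGAGGAGUUUAGAGCAAGUAA	107
CM1-m0006_3p	UAGUUUGAUUCACAGCACAAGA	17
CM1-m0007_3p	UCAAGGUCCGCCGUGAACACGC	12
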