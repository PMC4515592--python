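name	start	end	strand
ND1	3307	4262	+
ND2	4470	5511	+
CO1	5904	7445	+
CO2	7586	8269	+
ATP8	8366	8572	+
ATP6	8527	9207	+
CO3	9207	9990	+
ND3	10059	10404	+
ND4L	10470	10766	+
ND4	10760	12137	+
ND5	12337	14148	+
ND6	14149	14673	-
CYTB	14747	15887	+
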