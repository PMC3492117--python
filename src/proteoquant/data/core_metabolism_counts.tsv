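category	total_genes	detected_1plex	detected_4plex	detected_total	increased	decreased
Non-catalytic cellulosomal proteins	8	5	6	7	0	0
Cellulosomal glycosidases	73	29	26	31	2	1
Non-cellulosomal glycosidases	35	17	13	19	3	0
RsgI-like sigma factors and anti-sigma-I factors	9	3	2	3	0	0
Cello-oligosaccharide ABC transporters	14	9	8	10	2	1
Glycolysis	20	15	15	15	3	1
Pentose phosphate pathway	6	4	3	5	1	0
Energy storage	13	11	11	13	3	0
Pyruvate formation from phosphoenolpyruvate	8	8	8	8	0	2
End-product synthesis from pyruvate	49	39	38	41	12	0
Energy generation	17	14	14	14	2	1
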