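name	prediction_score	n_intermediates	drug_degree
Mozavaptan	100.0	1	12
Satavaptan	93.0	2	17
HET-0016	92.6	4	67
Pasireotide	90.6	2	28
Bosutinib	88.6	9	1088
EX-527	73.8	6	75
Pioglitazone	68.2	53	1994
Octreotide	67.2	257	2133
Roscovitine	65.8	58	1027
Pyrimethamine	65.0	88	1062
TRAM-34	65.0	25	109
Etanercept	64.2	163	521
Triptolide	60.2	135	4128
Rosiglitazone	59.4	316	666
U0126	55.2	188	5891
Menadione	52.2	138	2822
Curcumin	46.0	359	2653
Metformin	42.4	343	3616
Everolimus	35.0	174	986
Sirolimus	27.0	376	5621
Sorafenib	19.0	205	1446
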