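drug_id	name
C0077274	Triptolide
C2975283	Mozavaptan
C2607958	Satavaptan
C0028833	Octreotide
C1872203	Pasireotide
C1174836	SKI-606
C1516119	Sorafenib
C0755562	U0126
C1831731	Bosutinib
C0541315	Everolimus
C0072980	Sirolimus
C0025598	Metformin
C0071097	Pioglitazone
C0289313	Rosiglitazone
C0536217	Roscovitine
C0025270	Menadione
C0717758	Etanercept
C0034283	Pyrimethamine
CS221421	S3I-201
C1718383	Teriflunomide
C1957685	Genz-123346
C0968934	HET-0016
C0916207	TRAM-34
C0010467	Curcumin
C2935082	EX-527
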