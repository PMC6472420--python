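type_name	group_name
Pharmacologic Substance	Chemicals & Drugs
Enzyme	Chemicals & Drugs
Amino Acid, Peptide, or Protein	Chemicals & Drugs
Clinical Drug	Chemicals & Drugs
Disease or Syndrome	Disorders
Sign or Symptom	Disorders
Neoplastic Process	Disorders
Gene or Genome	Genes & Molecular Sequences
Cell	Anatomy
Body Part, Organ, or Organ Component	Anatomy
Tissue	Anatomy
Organism Function	Physiology
Molecular Function	Physiology
Cell Function	Physiology
Mammal	Living Beings
Bacterium	Living Beings
Laboratory Procedure	Procedures
Therapeutic or Preventive Procedure	Procedures
Medical Device	Devices
Natural Phenomenon or Process	Phenomena
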