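code	label
ECD	Experimental Conditions and Designs
GPED	Gene Expression Data
CPC	Cohort and Patient Characteristics
TLD	Experimental Characteristics or Transaction Log Data
CDD	Clinical Diagnostics Data
FAPA	Functional Annotation and Pathway Analysis
CGP	Comparative Genomics and Phylogenetics
DRP	Dose-Response or Pharmacokinetics
MAV	Genomic Mutation and Variant Data
MLD	Metabolomics and Lipidomic Data
AMP	Animal Model Phenotyping
IRD	Immune Response Data
SA	Survival Analysis
ED	Ecotoxicology Data
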