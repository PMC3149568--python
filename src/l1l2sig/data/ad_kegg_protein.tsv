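pathway	category	n_overlap	p_value
Cytokine-cytokine receptor interaction	Signaling Molecules and Interaction	14	9.69e-26
Cell adhesion molecules (CAMs)	Signaling Molecules and Interaction	1	7.59e-2
Neuroactive ligand-receptor interaction	Signaling Molecules and Interaction	1	1.67e-1
Hematopoietic cell lineage	Immune System	7	6.00e-14
Natural killer cell mediated cytotoxicity	Immune System	4	9.12e-7
Toll-like receptor signaling pathway	Immune System	3	2.19e-5
Fc epsilon RI signaling pathway	Immune System	2	1.01e-3
Leukocyte transendothelial migration	Immune System	2	2.29e-3
T cell receptor signaling pathway	Immune System	1	5.57e-2
Apoptosis	Cell Growth and Death	5	1.54e-9
MAPK signaling pathway	Signal Transduction	4	2.21e-5
Jak-STAT signaling pathway	Signal Transduction	4	1.90e-6
TGF-beta signaling pathway	Signal Transduction	1	4.96e-2
Adipocytokine signaling pathway	Endocrine System	3	1.13e-5
PPAR signaling pathway	Endocrine System	1	4.17e-2
Epithelial cell signaling in Helicobacter pylori infection	Infectious Diseases	2	8.05e-4
Gap junction	Cell Communication	2	1.33e-3
Focal adhesion	Cell Communication	2	6.43e-3
Glioma	Cancers	2	6.66e-4
Pancreatic cancer	Cancers	1	4.42e-2
Type I diabetes mellitus	Metabolic Diseases	2	2.96e-4
Type II diabetes mellitus	Metabolic Diseases	2	3.26e-4
Regulation of actin cytoskeleton	Cell Motility	2	6.89e-3
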