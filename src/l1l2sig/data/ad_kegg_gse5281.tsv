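pathway	category	n_overlap	p_value
Glycine, serine and threonine metabolism	Amino Acid Metabolism	1	3.20e-2
Tryptophan metabolism	Amino Acid Metabolism	1	5.88e-2
Metabolism of xenobiotics by cytochrome P450	Xenobiotics Biodegradation and Metabolism	1	4.23e-2
Neurodegenerative Diseases	Neurodegenerative Diseases	1	2.54e-2
Prion disease	Neurodegenerative Diseases	1	9.04e-3
MAPK signaling pathway	Signal Transduction	1	1.83e-1
Cytokine-cytokine receptor interaction	Signaling Molecules and Interaction	1	1.68e-1
ECM-receptor interaction	Signaling Molecules and Interaction	1	6.02e-2
Neuroactive ligand-receptor interaction	Signaling Molecules and Interaction	1	1.96e-1
Axon guidance	Development	1	8.77e-2
Antigen processing and presentation	Immune System	1	5.31e-2
Hematopoietic cell lineage	Immune System	1	6.17e-2
Leukocyte transendothelial migration	Immune System	1	8.14e-2
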