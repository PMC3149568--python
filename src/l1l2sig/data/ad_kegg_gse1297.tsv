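pathway	category	n_overlap	p_value
ECM-receptor interaction	Signaling Molecules and Interaction	3	2.39e-6
Neuroactive ligand-receptor interaction	Signaling Molecules and Interaction	2	3.93e-3
Cell Communication	Cell Communication	2	5.40e-4
Focal adhesion	Cell Communication	2	1.75e-3
MAPK signaling pathway	Signal Transduction	1	8.51e-2
Antigen processing and presentation	Immune System	1	2.37e-2
Hematopoietic cell lineage	Immune System	1	2.76e-2
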