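# The 12 stimulated primary human cell systems of the Diversity PLUS panel.
# columns: id	description	disease_relevance
id	description	disease_relevance
3C	Venular endothelial cells stimulated with TNFα, IL-1β, IFNγ	Cardiovascular disease, chronic inflammation
4H	Venular endothelial cells stimulated with IL-4, histamine	Autoimmunity, allergy, asthma
LPS	Venular endothelial cells and peripheral blood mononuclear cells stimulated with TLR4 ligand	Chronic inflammation, cardiovascular disease
SAg	Venular endothelial cells and peripheral blood mononuclear cells stimulated with TCR ligands	Chronic inflammation, autoimmune disease
BT	Peripheral blood mononuclear cells and B cells stimulated with αIgM and TCR ligands	Asthma, cancer, autoimmunity, allergy
BF4T	Bronchial epithelial cells and dermal fibroblasts stimulated with IL-4, TNFα	Fibrosis, lung inflammation, asthma, allergy
BE3C	Bronchial epithelial cells stimulated with IL-1β, IFNγ, TNFα	COPD, lung inflammation
CASM3C	Coronary artery smooth muscle cells stimulated with IL-1β, TNFα, IFNγ	Cardiovascular inflammation, restenosis
HDF3CGF	Dermal fibroblasts stimulated with IFNγ, TNFα, IL-1β, EGF, bFGF, PDGF-BB	Fibrosis, chronic inflammation
KF3CT	Keratinocytes and dermal fibroblasts stimulated with IL-1β, IFNγ, TGFβ, TNFα	Dermatitis, psoriasis
MyoF	Lung fibroblasts stimulated with TGFβ, TNFα	Wound healing, matrix remodeling, fibrosis, chronic inflammation
lMphg	Macrophages and venular endothelial cells stimulated with TLR2 ligand	Chronic inflammation, restenosis, cardiovascular disease
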