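# Synonym dictionary for biomarker names that appear under more than one
# spelling in the reference study's printed tables.  Lookup keys are folded
# (case, hyphens, whitespace removed); the right-hand column is the canonical
# display form.  Necessarily partial: only biomarkers appearing in the printed
# tables are covered.
# columns: variant	canonical
variant	canonical
PAI-I	PAI-1
PAI1	PAI-1
TIMP1	TIMP-1
Esel	E-selectin
Psel	P-selectin
Eot3	eotaxin-3
ITAC	I-TAC
Col-I	collagen-I
Col-III	collagen-III
Col-IV	collagen-IV
TM	thrombomodulin
TF	tissue factor
MMP9	MMP-9
MMP1	MMP-1
MMP3	MMP-3
sIgG	IgG
secreted IgG	IgG
sIL-17A	IL-17A
sIL-17F	IL-17F
sIL-2	IL-2
sIL-6	IL-6
sIL-10	IL-10
VEGFR	VEGFR2
fibrotic cell proliferation	fibroblast proliferation
Decorin	decorin
# identity entries register the canonical display form of every biomarker
# appearing in the reference tables, so only genuinely unknown names warn
HLA-DR	HLA-DR
MCP-1	MCP-1
CD38	CD38
CD40	CD40
CD69	CD69
VEGFR2	VEGFR2
IL-1α	IL-1α
IL-2	IL-2
IL-6	IL-6
IL-8	IL-8
IL-10	IL-10
IL-17A	IL-17A
IL-17F	IL-17F
TNFα	TNFα
IgG	IgG
tPA	tPA
uPAR	uPAR
EGFR	EGFR
M-CSF	M-CSF
MIG	MIG
IP-10	IP-10
VCAM-1	VCAM-1
SRB	SRB
alamarBlue	alamarBlue
PGE2	PGE2
MIP-1α	MIP-1α
T cell proliferation	T cell proliferation
B cell proliferation	B cell proliferation
endothelial cell proliferation	endothelial cell proliferation
fibroblast proliferation	fibroblast proliferation
coronary artery proliferation	coronary artery proliferation
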