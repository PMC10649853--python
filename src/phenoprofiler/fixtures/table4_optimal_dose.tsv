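# Significant activities at each compound's optimal dose, transcribed from the
# reference study's optimal-dose table (one row per printed arrow; biomarker
# spellings kept as printed, canonicalized at load time).
# columns: compound	dose_label	system	biomarker	direction
compound	dose_label	system	biomarker	direction
C15:0	17 uM	3C	MCP-1	down
C15:0	17 uM	3C	HLA-DR	down
C15:0	17 uM	3C	SRB	down
C15:0	17 uM	3C	endothelial cell proliferation	down
C15:0	17 uM	3C	thrombomodulin	up
C15:0	17 uM	3C	IL-8	down
C15:0	17 uM	4H	eotaxin-3	down
C15:0	17 uM	4H	VEGFR	down
C15:0	17 uM	LPS	MCP-1	down
C15:0	17 uM	LPS	VCAM-1	down
C15:0	17 uM	LPS	tissue factor	up
C15:0	17 uM	LPS	CD40	down
C15:0	17 uM	LPS	SRB	down
C15:0	17 uM	LPS	CD69	down
C15:0	17 uM	LPS	thrombomodulin	up
C15:0	17 uM	LPS	IL-1α	down
C15:0	17 uM	SAg	CD38	down
C15:0	17 uM	SAg	CD40	down
C15:0	17 uM	SAg	CD69	down
C15:0	17 uM	SAg	T cell proliferation	down
C15:0	17 uM	SAg	SRB	down
C15:0	17 uM	BT	sIgG	down
C15:0	17 uM	BT	sIL-17A	down
C15:0	17 uM	BT	sIL-17F	down
C15:0	17 uM	BT	TNFα	down
C15:0	17 uM	BE3C	PAI-I	down
C15:0	17 uM	BE3C	tPA	down
C15:0	17 uM	CASM3C	HLA-DR	down
C15:0	17 uM	CASM3C	VCAM-1	down
C15:0	17 uM	CASM3C	thrombomodulin	down
C15:0	17 uM	CASM3C	tissue factor	down
C15:0	17 uM	HDF3CGF	PAI-I	down
C15:0	17 uM	HDF3CGF	fibroblast proliferation	down
C15:0	17 uM	HDF3CGF	MCP-1	down
C15:0	17 uM	HDF3CGF	VCAM-1	down
C15:0	17 uM	HDF3CGF	IP-10	down
C15:0	17 uM	HDF3CGF	I-TAC	down
C15:0	17 uM	HDF3CGF	MIG	down
C15:0	17 uM	KF3CT	PAI-I	down
C15:0	17 uM	MyoF	VCAM-1	down
C15:0	17 uM	MyoF	collagen-I	down
C15:0	17 uM	MyoF	collagen-III	down
C15:0	17 uM	MyoF	collagen-IV	up
C15:0	17 uM	MyoF	decorin	down
C15:0	17 uM	MyoF	TIMP-1	down
C15:0	17 uM	/Mphg	sIL-10	down
C15:0	17 uM	/Mphg	CD40	down
C15:0	17 uM	/Mphg	MIP-1α	up
C15:0	17 uM	/Mphg	E-selectin	up
C15:0	17 uM	/Mphg	CD69	down
rapamycin	9 uM	3C	MCP-1	down
rapamycin	9 uM	3C	HLA-DR	down
rapamycin	9 uM	3C	SRB	down
rapamycin	9 uM	3C	endothelial cell proliferation	down
rapamycin	9 uM	3C	VCAM-1	down
rapamycin	9 uM	3C	uPAR	down
rapamycin	9 uM	4H	MCP-1	down
rapamycin	9 uM	4H	SRB	down
rapamycin	9 uM	LPS	MCP-1	down
rapamycin	9 uM	LPS	VCAM-1	down
rapamycin	9 uM	LPS	tissue factor	up
rapamycin	9 uM	LPS	CD40	down
rapamycin	9 uM	LPS	SRB	down
rapamycin	9 uM	LPS	M-CSF	down
rapamycin	9 uM	LPS	PGE2	up
rapamycin	9 uM	SAg	CD38	down
rapamycin	9 uM	SAg	CD40	down
rapamycin	9 uM	SAg	T cell proliferation	down
rapamycin	9 uM	SAg	SRB	down
rapamycin	9 uM	SAg	MCP-1	down
rapamycin	9 uM	BT	sIgG	down
rapamycin	9 uM	BT	sIL-17A	down
rapamycin	9 uM	BT	sIL-17F	down
rapamycin	9 uM	BT	TNFα	down
rapamycin	9 uM	BT	B cell proliferation	down
rapamycin	9 uM	BT	sIL-2	down
rapamycin	9 uM	BT	sIL-6	down
rapamycin	9 uM	BF4T	tPA	down
rapamycin	9 uM	BF4T	VCAM-1	down
rapamycin	9 uM	BE3C	PAI-I	down
rapamycin	9 uM	BE3C	MMP-1	up
rapamycin	9 uM	CASM3C	HLA-DR	down
rapamycin	9 uM	CASM3C	uPAR	down
rapamycin	9 uM	CASM3C	coronary artery proliferation	down
rapamycin	9 uM	HDF3CGF	PAI-I	down
rapamycin	9 uM	HDF3CGF	fibroblast proliferation	down
rapamycin	9 uM	HDF3CGF	EGFR	down
rapamycin	9 uM	KF3CT	PAI-I	down
rapamycin	9 uM	MyoF	VCAM-1	down
rapamycin	9 uM	MyoF	IL-8	up
rapamycin	9 uM	/Mphg	sIL-10	down
rapamycin	9 uM	/Mphg	E-selectin	down
metformin	5000 uM	3C	HLA-DR	down
metformin	5000 uM	3C	uPAR	down
metformin	5000 uM	3C	IL-8	down
metformin	5000 uM	4H	P-selectin	down
metformin	5000 uM	LPS	MCP-1	down
metformin	5000 uM	LPS	CD40	down
metformin	5000 uM	LPS	CD69	down
metformin	5000 uM	LPS	IL-1α	up
metformin	5000 uM	LPS	PGE2	up
metformin	5000 uM	LPS	TNFα	up
metformin	5000 uM	SAg	CD38	down
metformin	5000 uM	SAg	CD40	down
metformin	5000 uM	SAg	T cell proliferation	down
metformin	5000 uM	SAg	CD69	down
metformin	5000 uM	SAg	IL-8	down
metformin	5000 uM	BT	sIgG	down
metformin	5000 uM	BT	TNFα	down
metformin	5000 uM	BT	sIL-6	down
metformin	5000 uM	BF4T	tPA	down
metformin	5000 uM	BF4T	MCP-1	down
metformin	5000 uM	BF4T	eotaxin-3	down
metformin	5000 uM	BF4T	IL-8	down
metformin	5000 uM	BF4T	MMP-3	down
metformin	5000 uM	BF4T	MMP-9	down
metformin	5000 uM	BE3C	tPA	down
metformin	5000 uM	BE3C	IL-8	down
metformin	5000 uM	BE3C	HLA-DR	down
metformin	5000 uM	BE3C	MMP-9	down
metformin	5000 uM	HDF3CGF	VCAM-1	down
metformin	5000 uM	HDF3CGF	collagen-III	down
metformin	5000 uM	/Mphg	E-selectin	down
metformin	5000 uM	/Mphg	MCP-1	down
metformin	5000 uM	/Mphg	IL-8	down
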