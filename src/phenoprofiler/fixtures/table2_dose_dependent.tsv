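# Dose-dependent annotated activities per compound, transcribed from the
# reference study's summary table (one row per printed arrow; biomarker
# spellings kept as printed, canonicalized at load time).  Systems with a
# printed "None" cell have no rows.  direction: up/down.
# columns: compound	dose_label	system	biomarker	direction
compound	dose_label	system	biomarker	direction
C15:0	1.9-50 uM	3C	HLA-DR	down
C15:0	1.9-50 uM	3C	MCP-1	down
C15:0	1.9-50 uM	3C	proliferation	down
C15:0	1.9-50 uM	4H	Eot3	down
C15:0	1.9-50 uM	LPS	VEGFR2	down
C15:0	1.9-50 uM	LPS	MCP-1	down
C15:0	1.9-50 uM	LPS	CD69	down
C15:0	1.9-50 uM	LPS	IL-1α	down
C15:0	1.9-50 uM	SAg	CD38	down
C15:0	1.9-50 uM	SAg	CD40	down
C15:0	1.9-50 uM	SAg	CD69	down
C15:0	1.9-50 uM	SAg	T cell proliferation	down
C15:0	1.9-50 uM	BT	IgG	down
C15:0	1.9-50 uM	BT	IL-17F	down
C15:0	1.9-50 uM	BE3C	tPA	down
C15:0	1.9-50 uM	CASM3C	HLA-DR	down
C15:0	1.9-50 uM	CASM3C	IL-6	down
C15:0	1.9-50 uM	CASM3C	VCAM-1	down
C15:0	1.9-50 uM	CASM3C	TM	down
C15:0	1.9-50 uM	CASM3C	TF	down
C15:0	1.9-50 uM	CASM3C	proliferation	down
C15:0	1.9-50 uM	HDF3CGF	PAI-1	down
C15:0	1.9-50 uM	HDF3CGF	VCAM-1	down
C15:0	1.9-50 uM	HDF3CGF	IP-10	down
C15:0	1.9-50 uM	HDF3CGF	ITAC	down
C15:0	1.9-50 uM	HDF3CGF	MIG	down
C15:0	1.9-50 uM	HDF3CGF	fibroblast proliferation	down
C15:0	1.9-50 uM	MyoF	VCAM-1	down
C15:0	1.9-50 uM	MyoF	Col-I	down
C15:0	1.9-50 uM	MyoF	IL-8	down
C15:0	1.9-50 uM	MyoF	Decorin	down
C15:0	1.9-50 uM	MyoF	TIMP-1	down
C15:0	1.9-50 uM	/Mphg	CD40	down
C15:0	1.9-50 uM	/Mphg	CD69	down
rapamycin	0.3-9 uM	3C	HLA-DR	down
rapamycin	0.3-9 uM	3C	VCAM-1	down
rapamycin	0.3-9 uM	3C	uPAR	down
rapamycin	0.3-9 uM	3C	proliferation	down
rapamycin	0.3-9 uM	4H	MCP-1	down
rapamycin	0.3-9 uM	LPS	CD40	down
rapamycin	0.3-9 uM	SAg	CD38	down
rapamycin	0.3-9 uM	SAg	CD40	down
rapamycin	0.3-9 uM	SAg	MCP-1	down
rapamycin	0.3-9 uM	SAg	T cell proliferation	down
rapamycin	0.3-9 uM	BT	IgG	down
rapamycin	0.3-9 uM	BT	IL-17F	down
rapamycin	0.3-9 uM	BT	TNFα	down
rapamycin	0.3-9 uM	BT	IL-6	down
rapamycin	0.3-9 uM	BT	IL-2	down
rapamycin	0.3-9 uM	BT	IL-17A	down
rapamycin	0.3-9 uM	BT	proliferation	down
rapamycin	0.3-9 uM	BF4T	VCAM-1	down
rapamycin	0.3-9 uM	BF4T	tPA	down
rapamycin	0.3-9 uM	BE3C	tPA	down
rapamycin	0.3-9 uM	CASM3C	HLA-DR	down
rapamycin	0.3-9 uM	CASM3C	uPAR	down
rapamycin	0.3-9 uM	CASM3C	proliferation	down
rapamycin	0.3-9 uM	HDF3CGF	PAI-I	down
rapamycin	0.3-9 uM	HDF3CGF	EGFR	down
rapamycin	0.3-9 uM	HDF3CGF	fibroblast proliferation	down
rapamycin	0.3-9 uM	KF3CT	PAI-I	down
rapamycin	0.3-9 uM	MyoF	VCAM-1	down
rapamycin	0.3-9 uM	MyoF	PAI-I	down
rapamycin	0.3-9 uM	/Mphg	sIL-10	down
metformin	190-5000 uM	3C	HLA-DR	down
metformin	190-5000 uM	3C	IL-8	down
metformin	190-5000 uM	LPS	CD40	down
metformin	190-5000 uM	SAg	CD38	down
metformin	190-5000 uM	SAg	CD69	down
metformin	190-5000 uM	SAg	T cell proliferation	down
metformin	190-5000 uM	BF4T	MCP-1	down
metformin	190-5000 uM	BF4T	tPA	down
metformin	190-5000 uM	BE3C	IP-10	down
metformin	190-5000 uM	BE3C	IL-8	down
metformin	190-5000 uM	BE3C	HLA-DR	down
metformin	190-5000 uM	BE3C	MMP9	down
metformin	190-5000 uM	HDF3CGF	Col-III	down
metformin	190-5000 uM	/Mphg	MCP-1	down
metformin	190-5000 uM	/Mphg	Esel	down
metformin	190-5000 uM	/Mphg	IL-8	down
acarbose	1.1-30 uM	CASM3C	uPAR	down
acarbose	1.1-30 uM	HDF3CGF	EGFR	down
acarbose	1.1-30 uM	HDF3CGF	fibroblast proliferation	down
acarbose	1.1-30 uM	MyoF	Col-IV	down
acarbose	1.1-30 uM	MyoF	TIMP1	down
EPA	1.9-17 uM	3C	MCP-1	down
EPA	1.9-17 uM	3C	uPAR	down
EPA	1.9-17 uM	BF4T	PAI-I	down
EPA	1.9-17 uM	HDF3CGF	PAI-I	down
EPA	1.9-17 uM	HDF3CGF	M-CSF	down
EPA	1.9-17 uM	MyoF	Col-I	down
EPA	1.9-17 uM	MyoF	Col-III	down
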