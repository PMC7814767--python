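label	network	hemisphere	alias_network	mni_x	mni_y	mni_z
LFEF	DAN	L
RFEF	DAN	R
LvIPS	DAN	L
RvIPS	DAN	R
LpIPS	DAN	L
RpIPS	DAN	R
LMT	DAN	L
RMT	DAN	R
RVFC	VAN	R
RMFG	VAN	R
RSTG	VAN	R
RSMG	VAN	R
PCC	DMN	M
RMPFC	DMN	R
LAG	DMN	L
RAG	DMN	R
LITG	DMN	L	LAN
RITG	DMN	R
LCS	SMN	L
RCS	SMN	R
LS2	SMN	L
RS2	SMN	R
LSMA	SMN	L
RSMA	SMN	R
F3OPD	LAN	L
F3TV	LAN	L
LDIFG	LAN	L
T1a	LAN	L
T1p	LAN	L
STS	LAN	L
LV1	VIN	L
RV1	VIN	R
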