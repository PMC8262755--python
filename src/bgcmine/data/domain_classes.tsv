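# profile_name	domain_class
ACP	ACP
AMP-binding	A
AT_mal	AT
AT_mmal	AT
A_gly	A
A_ser	A
A_val	A
Condensation	C
Epimerization	E
PCP	PCP
PKS_AT	AT
PKS_DH	DH
PKS_ER	ER
PKS_KR	KR
PKS_KS	KS
Thioesterase	TE
cMT	MT
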