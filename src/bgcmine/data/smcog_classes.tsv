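# profile_name	smcog_class
ABC_transporter	SMCOG1000:ABC-transporter
LuxR_regulator	SMCOG1031:LuxR-family-regulator
MFS_transporter	SMCOG1005:MFS-transporter
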