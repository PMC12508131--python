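signature	etiology
SBS_SYN_CLOCK	Clock_like
SBS_SYN_THIO	Chemotherapy
SBS_SYN_MMR	MMR
SBS_SYN_APOBEC	APOBEC_AID
SBS_SYN_UV	UV
SBS_SYN_UNKNOWN	Unknown
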