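gene	operon
g_aceA	aceBAK
g_aceB	aceBAK
g_aceE	aceEF
g_aceF	aceEF
g_ackA	pta-ackA
g_acs	acs
g_actP	acs
g_amtB	amtB
g_fut1	fut
g_fut2	fut
g_fut3	fut
g_glpD	glpD
g_glpF	glpFK
g_glpK	glpFK
g_gltA	gltA
g_gpsA	gpsA
g_icd	icd
g_lpd	aceEF
g_pck	pck
g_ppc	ppc
g_pta	pta-ackA
g_ptsG	ptsHI-crr
g_ptsH	ptsHI-crr
g_pykA	pykA
g_pykF	pykF
g_sucA	sucAB
g_sucB	sucAB
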