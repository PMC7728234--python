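gene	regulon
g_aceA	iclR
g_aceB	iclR
g_aceE	pdhR
g_aceF	pdhR
g_ackA	fnr
g_acs	crp
g_actP	crp
g_glpD	glpR
g_glpF	glpR
g_glpK	glpR
g_gltA	arcA
g_gltA	crp
g_gpsA	glpR
g_icd	arcA
g_lpd	fnr
g_lpd	pdhR
g_pta	fnr
g_ptsG	crp
g_ptsH	crp
g_pykA	fruR
g_pykF	fruR
g_sucA	arcA
g_sucB	arcA
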