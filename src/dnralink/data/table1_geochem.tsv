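site_id	salinity_ppt	bw_no3_uM	bw_nh4_uM	pct_organic	h2s_uM	nox_uM	extractable_nh4_umol_g
AA2	9.1	0.44	7.8	15.57	0.90	0.26	0.06
JAX	17.8	0.25	0.75	17.98	486.90	0.23	0.21
M47	16.4	0.37	1.18	18.95	249.87	0.54	0.28
M31	27.0	0.47	1.45	10.19	3.21	0.33	0.20
M15	33.6	0.62	1.32	0.33	0.20	0.72	0.04
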