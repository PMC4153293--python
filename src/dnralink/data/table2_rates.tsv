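site_id	dnra_rate_nmol_n_g_h	dnra_rate_se	nrfa_copies_per_g	nrfa_copies_se
AA2	13.8	1.8	7.72e8	4.76e7
JAX	20.7	0.02	2.58e9	6.27e7
M47	22.6	1.0	1.56e9	2.68e8
M31	25.1	3.4	2.18e9	3.16e8
M15	2.2	0.8	2.31e8	2.50e7
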