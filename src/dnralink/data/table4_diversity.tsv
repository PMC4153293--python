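site_id	unique	otus	chao1	ace	shannon_h	evenness_j
AA2	2052	1012	1958.6	2162.3	6.507	0.940
JAX	1714	827	1569.5	1638.0	6.298	0.938
M47	2022	799	1237.8	1381.5	6.188	0.926
M31	2210	1005	1897.8	2106.9	6.360	0.920
M15	2157	933	1489.9	1603.5	6.446	0.943
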