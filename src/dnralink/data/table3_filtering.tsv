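site_id	initial_rdp	denoise_chimera	frambot	valid	pct_dominant	pct_endemic
AA2	7918	7557	7483	7346	42.3	30.9
JAX	8821	7940	7910	7852	50.7	11.7
M47	13870	13464	13130	12952	46.8	13.6
M31	11197	10243	10218	10000	50.2	16.7
M15	9076	8387	8330	8015	38.6	39.8
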