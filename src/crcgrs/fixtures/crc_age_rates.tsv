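age_lower	age_upper	rate
40	45	0.00015
45	50	0.00025
50	55	0.00042
55	60	0.00065
60	65	0.00095
65	70	0.00135
70	75	0.00175
75	80	0.00210
80	85	0.00240
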