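fh_category	relative_risk
0	1.0
1	2.2
2	3.8
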