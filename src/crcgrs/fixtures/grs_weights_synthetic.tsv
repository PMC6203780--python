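snp_id	effect_allele	log_or
rs76989256	G	-0.0580
rs26013607	C	0.0476
rs84276873	A	0.1657
rs18962705	T	-0.0309
rs72791405	A	-0.0830
rs85979818	A	-0.0553
rs83301947	A	-0.0128
rs79612407	T	-0.0089
rs63975013	A	-0.0742
rs83663613	C	0.0187
rs92843785	T	0.0166
rs24051429	C	-0.0122
rs80173003	C	0.1197
rs32478660	T	-0.1241
rs68245121	T	-0.0421
rs64440515	G	-0.0455
rs73433032	T	-0.0851
rs28239096	G	-0.1005
rs55753022	T	0.0677
rs8831933	C	-0.1043
rs78885806	G	-0.1521
rs10639377	A	0.0620
rs69907105	C	-0.1571
rs13238602	G	0.0816
rs33627026	C	-0.0990
rs28486609	A	-0.0531
rs57842341	A	-0.0700
rs61199583	T	-0.0870
rs38643160	C	-0.0852
rs88867014	C	0.0159
rs62976756	A	0.0500
rs67397002	T	-0.1653
rs38246597	A	0.1029
rs63399097	G	0.0520
rs88996632	C	0.0189
rs54373351	C	-0.2224
rs33990058	G	0.0157
rs28992430	C	-0.0378
rs12214305	A	0.0129
rs79826548	T	-0.0116
rs4664970	G	0.0488
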