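species	N_inf	L	database
A. thaliana	487	959	BIND
B. taurus	129	107	DIP
C. elegans	3227	5026	BIND
D. melanogaster	7910	23128	BIND
E. coli	399	312	BIND
H. pylori	724	1403	COSIN
H. sapiens	2529	3376	DIP
M. musculus	1003	994	DIP
R. norvegicus	349	304	DIP
S. cerevisiae	4135	7839	COSIN
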