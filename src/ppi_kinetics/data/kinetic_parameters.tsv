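parameter	best	mean_top10	se_percent_top10
ki	8.61692	12.683567	10.1
k2	0.122669	0.052556819	27.7
kXY	0.0611168	0.09274057	10.4
kYX	2.8542	4.249004	10.1
xi0	0.426372	0.4256051	0.1
mu	0.00237779	0.003526257	10.1
delta_eps	10.6696	15.91212	9.9
r	0.107993	0.204924912	45.9
f0	34376.8	51108.95	10.1
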