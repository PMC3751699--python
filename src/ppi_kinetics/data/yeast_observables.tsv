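quantity	estimate	se_percent
A1	3184.82	32
A2	49.8628	77
beta1	4.80485	29
beta2	2.1242	20
xi_r	6.30779	51
p1	0.73526	13
p2	0.000552383	5
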