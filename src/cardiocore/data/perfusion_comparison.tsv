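experiment	label	sim_vO2	sim_vs	exp_vO2	exp_vs
1	glucose	3.60	0.60	4.28	0.55
2.1	lactate	3.81	1.17	4.71	1.41
2.2	glucose+lactate	3.73	0.96	4.70	1.59
3.1	oleate	4.11	0.16	4.94	0.18
3.2	glucose+oleate	4.02	0.24	4.36	0.21
4.1	acetate	4.80	2.40	4.28	1.68
4.2	glucose+acetate	4.60	2.11	4.69	1.46
5.1	acetoacetate	3.93	0.98	4.20	0.53
5.2	glucose+acetoacetate	3.81	0.86	4.95	1.01
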