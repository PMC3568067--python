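beta_glucose	beta_oleate	beta_acetoacetate	beta_lactate	vO2	vs
0.00	1.00	0.00	0.00	4.1101	0.1626
1.00	0.00	0.00	0.00	3.6007	0.6005
0.00	0.00	1.00	0.00	3.9269	0.9806
0.00	0.00	0.00	1.00	3.8124	1.2701
0.79	0.21	0.00	0.00	3.8534	0.3823
0.42	0.37	0.09	0.12	3.9830	0.3154
0.33	0.19	0.43	0.05	3.9420	0.4536
0.20	0.16	0.26	0.38	3.9485	0.5292
0.46	0.03	0.46	0.05	3.7757	0.6847
0.17	0.09	0.01	0.73	3.8880	0.7020
0.20	0.04	0.41	0.35	3.8534	0.7841
0.16	0.03	0.33	0.48	3.8448	0.8575
0.06	0.05	0.03	0.86	3.8794	0.8942
0.02	0.02	0.52	0.44	3.9010	0.9677
0.07	0.00	0.07	0.86	3.7930	1.1556
0.00	0.00	0.13	0.87	3.8297	1.2247
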