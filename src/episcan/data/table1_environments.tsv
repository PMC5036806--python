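env_id	parent_a	parent_b	mean	min	max	sd	kurtosis	skewness
2002HRB	19.63	21.83	21.48	16.68	24.33	1.39	0.25	-0.36
2003HRB	19.27	19.68	20.46	17.90	22.61	0.91	-0.02	-0.08
2004HRB	19.03	19.26	19.28	17.87	20.92	0.60	-0.20	0.17
2005HRB	19.11	19.44	19.33	16.99	22.17	1.08	-0.30	0.37
2006HRB	20.30	21.20	20.86	19.05	21.90	0.50	0.46	-0.52
2007HRB	20.97	21.26	21.46	19.49	23.35	0.81	-0.10	0.07
2007HXL	21.09	21.63	22.40	18.99	25.88	1.36	-0.12	-0.01
2007JMS	20.65	20.98	20.99	18.64	22.76	0.77	0.44	-0.45
2008HRB	21.89	20.31	21.67	18.64	23.57	0.89	0.28	-0.43
2008HXL	21.80	19.89	21.02	18.64	23.59	0.82	0.83	0.58
2008JMS	21.77	20.73	22.19	19.38	24.13	0.90	0.67	-0.59
2009HRB	21.36	20.26	20.68	18.32	21.79	0.61	1.96	-1.15
2009HXL	21.24	18.96	20.42	17.85	22.28	0.67	1.37	-0.92
2009JMS	20.93	20.07	20.92	19.01	21.98	0.50	1.57	-0.59
2010HRB	21.21	21.42	21.37	19.73	22.03	0.41	2.63	1.27
2010HXL	21.73	21.42	21.56	20.14	22.36	0.39	1.27	0.69
2010JMS	21.51	21.49	21.49	19.09	23.20	0.48	4.64	0.80
2011HRB	20.56	21.14	21.33	20.01	22.51	0.40	0.55	-0.26
2011HXL	19.98	21.40	21.21	20.17	22.34	0.43	-0.22	-0.26
2011JMS	19.78	20.99	21.41	20.57	22.55	0.36	1.12	0.63
2012HRB	21.29	21.49	20.56	18.02	22.74	0.86	2.09	-0.42
2012HXL	20.73	21.16	19.07	15.51	20.86	0.43	1.85	-0.86
2012JMS	19.58	19.70	21.02	18.58	22.45	0.36	2.51	-0.66
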