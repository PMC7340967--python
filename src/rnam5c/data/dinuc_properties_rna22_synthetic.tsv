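property	AA	AC	AG	AU	CA	CC	CG	CU	GA	GC	GG	GU	UA	UC	UG	UU
Shift	-0.08	0.23	-0.04	-0.06	0.11	-0.01	0.3	-0.04	0.07	0.07	-0.01	0.23	-0.02	0.07	0.11	-0.08
Slide	-1.27	-1.43	-1.5	-1.36	-1.46	-1.78	-1.89	-1.5	-1.7	-1.39	-1.78	-1.43	-1.45	-1.7	-1.46	-1.27
Rise	3.18	3.24	3.3	3.24	3.09	3.32	3.3	3.3	3.38	3.22	3.32	3.24	3.26	3.38	3.09	3.18
Tilt	-0.8	0.8	0.5	1.1	1.0	0.3	-0.1	0.5	1.3	0.0	0.3	0.8	-0.2	1.3	1.0	-0.8
Roll	7.0	4.8	8.5	7.1	9.9	8.7	12.1	8.5	9.4	6.1	8.7	4.8	10.7	9.4	9.9	7.0
Twist	31	32	30	33	31	32	27	30	32	35	32	32	32	32	31	31
Stacking energy	-5.37	-10.51	-6.78	-5.37	-6.57	-8.26	-9.61	-6.78	-13.94	-14.59	-8.26	-10.51	-3.21	-13.94	-6.57	-5.37
Enthalpy	-6.82	-11.4	-10.48	-9.38	-10.44	-13.39	-10.64	-10.48	-12.44	-14.88	-13.39	-11.4	-7.69	-12.44	-10.44	-6.82
Entropy	-19.0	-29.5	-27.1	-26.7	-26.9	-32.7	-26.7	-27.1	-32.5	-36.9	-32.7	-29.5	-20.5	-32.5	-26.9	-19.0
Free energy	-0.93	-2.24	-2.08	-1.1	-2.11	-3.26	-2.36	-2.08	-2.35	-3.42	-3.26	-2.24	-1.33	-2.35	-2.11	-0.93
Enthalpy1	-6.6	-10.2	-7.6	-5.7	-10.5	-12.2	-8.0	-7.6	-13.3	-14.2	-12.2	-10.2	-8.1	-13.3	-10.5	-6.6
Entropy1	-18.38	-26.12	-19.02	-15.48	-28.05	-29.99	-19.35	-19.02	-35.47	-34.82	-29.99	-26.12	-22.57	-35.47	-28.05	-18.38
Free energy1	-0.9	-2.1	-1.7	-0.9	-1.8	-2.9	-2.0	-1.7	-2.3	-3.4	-2.9	-2.1	-1.1	-2.3	-1.8	-0.9
Hydrophilicity	0.023	0.083	0.035	0.09	0.118	0.349	0.193	0.378	0.048	0.146	0.065	0.16	0.112	0.359	0.224	0.389
Adenine content	2	1	1	1	1	0	0	0	1	0	0	0	1	0	0	0
Cytosine content	0	1	0	0	1	2	1	1	0	1	0	0	0	1	0	0
Guanine content	0	0	1	0	0	0	1	0	1	1	2	1	0	0	1	0
Uracil content	0	0	0	1	0	0	0	1	0	0	0	1	1	1	1	2
GC content	0	1	1	0	1	2	2	1	1	2	2	1	0	1	1	0
Purine content	2	1	2	1	1	0	1	0	2	1	2	1	1	0	1	0
Keto content	0	0	1	1	0	0	1	1	1	1	2	2	1	1	2	2
Amino content	2	2	1	1	2	2	1	1	1	1	0	0	1	1	0	0
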