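dinucleotide	enthalpy	enthalpy2	entropy	entropy2	free_energy	free_energy2	hydrophilicity	hydrophilicity2	rise	roll	shift	slide	stackingenergy	tilt	twist
AA	-6.6	-6.82	-18.4	-19.0	-0.9	-0.93	0.023	0.04	3.18	7.0	-0.08	-1.27	-13.7	-0.8	31.0
AC	-10.2	-11.40	-26.2	-31.5	-2.1	-2.24	0.083	0.14	3.24	4.8	0.23	-1.43	-13.8	0.8	32.0
AG	-7.6	-10.48	-19.2	-27.1	-1.7	-2.08	0.035	0.08	3.30	8.5	-0.04	-1.50	-14.0	0.5	30.0
AU	-5.7	-9.38	-15.5	-26.7	-0.9	-1.10	0.090	0.14	3.24	7.1	-0.06	-1.36	-15.4	1.1	33.0
CA	-10.5	-10.44	-27.8	-26.9	-1.8	-2.11	0.118	0.21	3.09	9.9	0.11	-1.46	-14.4	1.0	31.0
CC	-12.2	-13.39	-29.7	-32.7	-2.9	-3.26	0.349	0.49	3.32	8.7	-0.01	-1.78	-11.1	0.3	32.0
CG	-8.0	-10.64	-19.4	-26.7	-2.0	-2.36	0.193	0.35	3.30	12.1	0.30	-1.89	-15.6	-0.1	27.0
CU	-7.6	-10.48	-19.2	-27.1	-1.7	-2.08	0.378	0.52	3.30	8.5	-0.04	-1.50	-14.0	0.5	30.0
GA	-13.3	-12.44	-35.5	-32.5	-2.3	-2.35	0.048	0.10	3.38	9.4	0.07	-1.70	-14.2	1.3	32.0
GC	-14.2	-14.88	-34.9	-36.9	-3.4	-3.42	0.146	0.26	3.22	6.1	0.07	-1.39	-16.9	0.0	35.0
GG	-12.2	-13.39	-29.7	-32.7	-2.9	-3.26	0.065	0.17	3.32	8.7	-0.01	-1.78	-11.1	0.3	32.0
GU	-10.2	-11.40	-26.2	-31.5	-2.1	-2.24	0.160	0.27	3.24	4.8	0.23	-1.43	-13.8	0.8	32.0
UA	-8.1	-7.69	-22.6	-20.5	-1.1	-1.33	0.112	0.21	3.26	10.7	-0.02	-1.45	-16.0	-0.2	32.0
UC	-13.3	-12.44	-35.5	-32.5	-2.3	-2.35	0.359	0.48	3.38	9.4	0.07	-1.70	-14.2	1.3	32.0
UG	-10.5	-10.44	-27.8	-26.9	-1.8	-2.11	0.224	0.34	3.09	9.9	0.11	-1.46	-14.4	1.0	31.0
UU	-6.6	-6.82	-18.4	-19.0	-0.9	-0.93	0.389	0.44	3.18	7.0	-0.08	-1.27	-13.7	-0.8	31.0
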