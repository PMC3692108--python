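property	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
twist	35.62	34.4	27.7	31.5	34.5	33.67	29.8	27.7	36.9	40.0	33.67	34.4	36.0	36.9	34.5	35.62
tilt	-1.4	-0.1	-1.7	0.0	0.5	-0.1	0.0	-1.7	-1.5	0.0	-0.1	-0.1	0.0	-1.5	0.5	-1.4
roll	0.3	0.5	4.5	-0.8	4.7	3.6	5.4	4.5	1.9	0.3	3.6	0.5	3.3	1.9	4.7	0.3
shift	-0.03	-0.13	0.09	0.0	0.09	0.05	0.0	0.09	-0.28	0.0	0.05	-0.13	0.0	-0.28	0.09	-0.03
slide	-0.08	-0.58	-0.25	-0.59	0.53	-0.22	0.41	-0.25	0.09	0.05	-0.22	-0.58	0.05	0.09	0.53	-0.08
rise	3.16	3.41	3.63	3.89	3.23	3.06	3.60	3.63	3.47	3.98	3.06	3.41	3.21	3.47	3.23	3.16
stacking_energy	-5.37	-10.51	-6.78	-6.57	-6.57	-8.26	-9.61	-6.78	-9.81	-14.59	-8.26	-10.51	-3.82	-9.81	-6.57	-5.37
enthalpy	-7.9	-8.4	-7.8	-7.2	-8.5	-8.0	-10.6	-7.8	-8.2	-9.8	-8.0	-8.4	-7.2	-8.2	-8.5	-7.9
entropy	-22.2	-22.4	-21.0	-20.4	-22.7	-19.9	-27.2	-21.0	-22.2	-24.4	-19.9	-22.4	-21.3	-22.2	-22.7	-22.2
free_energy	-1.00	-1.44	-1.28	-0.88	-1.45	-1.84	-2.17	-1.28	-1.30	-2.24	-1.84	-1.44	-0.58	-1.30	-1.45	-1.00
propeller_twist	-18.66	-13.10	-14.00	-15.01	-9.45	-8.11	-10.03	-14.00	-13.48	-11.08	-8.11	-13.10	-11.85	-13.48	-9.45	-18.66
melting_temperature	54.50	97.73	58.42	57.02	54.71	85.97	72.55	58.42	86.44	136.12	85.97	97.73	36.73	86.44	54.71	54.50
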