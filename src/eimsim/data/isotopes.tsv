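# eimsim isotope & element reference table, version 1
# columns: symbol	atomic_number	covalent_radius_A	mass_number	exact_mass_u	abundance
# Exact masses and isotopic abundances: IUPAC/CIAAW representative values (AME2020
# masses, CIAAW 2021 abundances, rounded). Covalent radii: Cordero et al. 2008
# single-bond radii (low-spin value for Fe). Abundances per element sum to 1.
# H: CIAAW
H	1	0.31	1	1.007825	0.999885
H	1	0.31	2	2.014102	0.000115
# He: CIAAW
He	2	0.28	3	3.016029	0.00000134
He	2	0.28	4	4.002603	0.99999866
# B: CIAAW
B	5	0.84	10	10.012937	0.199
B	5	0.84	11	11.009305	0.801
# C: CIAAW
C	6	0.76	12	12.000000	0.9893
C	6	0.76	13	13.003355	0.0107
# N: CIAAW
N	7	0.71	14	14.003074	0.99636
N	7	0.71	15	15.000109	0.00364
# O: CIAAW
O	8	0.66	16	15.994915	0.99757
O	8	0.66	17	16.999132	0.00038
O	8	0.66	18	17.999160	0.00205
# F: CIAAW (monoisotopic)
F	9	0.57	19	18.998403	1.0
# Na: CIAAW (monoisotopic)
Na	11	1.66	23	22.989770	1.0
# Mg: CIAAW
Mg	12	1.41	24	23.985042	0.7899
Mg	12	1.41	25	24.985837	0.1000
Mg	12	1.41	26	25.982593	0.1101
# Al: CIAAW (monoisotopic)
Al	13	1.21	27	26.981538	1.0
# Si: CIAAW
Si	14	1.11	28	27.976927	0.92223
Si	14	1.11	29	28.976495	0.04685
Si	14	1.11	30	29.973770	0.03092
# P: CIAAW (monoisotopic)
P	15	1.07	31	30.973762	1.0
# S: CIAAW
S	16	1.05	32	31.972071	0.9499
S	16	1.05	33	32.971459	0.0075
S	16	1.05	34	33.967867	0.0425
S	16	1.05	36	35.967081	0.0001
# Cl: CIAAW
Cl	17	1.02	35	34.968853	0.7576
Cl	17	1.02	37	36.965903	0.2424
# Cr: CIAAW
Cr	24	1.39	50	49.946044	0.04345
Cr	24	1.39	52	51.940508	0.83789
Cr	24	1.39	53	52.940649	0.09501
Cr	24	1.39	54	53.938880	0.02365
# Fe: CIAAW; radius = Cordero low-spin
Fe	26	1.32	54	53.939611	0.05845
Fe	26	1.32	56	55.934938	0.91754
Fe	26	1.32	57	56.935394	0.02119
Fe	26	1.32	58	57.933276	0.00282
# Ni: CIAAW
Ni	28	1.24	58	57.935343	0.680769
Ni	28	1.24	60	59.930786	0.262231
Ni	28	1.24	61	60.931056	0.011399
Ni	28	1.24	62	61.928345	0.036345
Ni	28	1.24	64	63.927966	0.009256
# Cu: CIAAW
Cu	29	1.32	63	62.929597	0.6915
Cu	29	1.32	65	64.927790	0.3085
# Ge: CIAAW
Ge	32	1.20	70	69.924247	0.2057
Ge	32	1.20	72	71.922076	0.2745
Ge	32	1.20	73	72.923459	0.0775
Ge	32	1.20	74	73.921178	0.3650
Ge	32	1.20	76	75.921403	0.0773
# As: CIAAW (monoisotopic)
As	33	1.19	75	74.921596	1.0
# Se: CIAAW
Se	34	1.20	74	73.922476	0.0089
Se	34	1.20	76	75.919214	0.0937
Se	34	1.20	77	76.919914	0.0763
Se	34	1.20	78	77.917309	0.2377
Se	34	1.20	80	79.916521	0.4961
Se	34	1.20	82	81.916699	0.0873
# Br: CIAAW
Br	35	1.20	79	78.918338	0.5069
Br	35	1.20	81	80.916291	0.4931
# Sn: CIAAW
Sn	50	1.39	112	111.904818	0.0097
Sn	50	1.39	114	113.902779	0.0066
Sn	50	1.39	115	114.903342	0.0034
Sn	50	1.39	116	115.901741	0.1454
Sn	50	1.39	117	116.902952	0.0768
Sn	50	1.39	118	117.901603	0.2422
Sn	50	1.39	119	118.903308	0.0859
Sn	50	1.39	120	119.902195	0.3258
Sn	50	1.39	122	121.903439	0.0463
Sn	50	1.39	124	123.905274	0.0579
# Sb: CIAAW
Sb	51	1.39	121	120.903816	0.5721
Sb	51	1.39	123	122.904214	0.4279
# Te: CIAAW
Te	52	1.38	120	119.904020	0.0009
Te	52	1.38	122	121.903044	0.0255
Te	52	1.38	123	122.904270	0.0089
Te	52	1.38	124	123.902818	0.0474
Te	52	1.38	125	124.904431	0.0707
Te	52	1.38	126	125.903312	0.1884
Te	52	1.38	128	127.904463	0.3174
Te	52	1.38	130	129.906224	0.3408
# I: CIAAW (monoisotopic)
I	53	1.39	127	126.904473	1.0
# Pb: CIAAW
Pb	82	1.46	204	203.973044	0.014
Pb	82	1.46	206	205.974465	0.241
Pb	82	1.46	207	206.975897	0.221
Pb	82	1.46	208	207.976652	0.524
# Bi: CIAAW (monoisotopic)
Bi	83	1.48	209	208.980399	1.0
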