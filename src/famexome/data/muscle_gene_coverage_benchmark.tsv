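gene	total_bases	failed_all_cases	pct_all_cases	pct_case_1	pct_case_2	pct_case_3	pct_case_4	pct_case_5
BIN1	2227	672	30.18	52.76	42.30	46.88	48.54	64.08
COL6A1	3787	1106	29.21	42.83	40.22	44.97	37.39	53.45
COL6A2	3962	853	21.53	36.90	35.41	36.19	33.52	46.67
CRYAB	588	223	37.93	37.93	37.93	37.93	37.93	37.93
DES	1593	552	34.65	35.72	38.04	39.80	38.42	40.36
DPM3	389	1	0.26	0.26	1.03	0.51	5.40	33.68
FKRP	1508	1336	88.59	97.35	100.00	95.16	93.04	100.00
GAA	3239	499	15.41	32.94	23.87	28.93	19.76	41.40
JUP	2498	632	25.30	40.07	28.38	36.51	42.31	47.92
KBTBD13	1397	966	69.15	87.54	84.54	80.67	72.01	94.13
LMNA	2256	487	21.59	29.30	25.93	32.80	36.57	66.80
MYBPC3	4505	866	19.22	32.65	27.48	30.17	29.77	43.64
PABPN1	1061	347	32.70	35.63	35.63	44.39	45.33	48.35
PLEC	15508	5934	38.26	51.62	47.47	55.42	42.84	52.12
POMT2	2673	712	26.64	29.55	28.77	26.79	33.56	34.04
SEPN1	2033	560	27.55	28.63	28.14	28.82	27.94	31.23
SGCA	1344	358	26.64	34.38	31.10	35.04	30.80	30.13
SIL1	1566	244	15.58	25.93	22.22	22.73	25.48	34.42
SMN1	1045	975	93.30	93.30	93.30	93.30	93.30	93.30
TAZ	1099	245	22.29	40.58	33.76	30.66	40.22	22.75
TNNI3	793	119	15.01	37.45	24.34	34.68	21.94	50.06
TNNT1	1097	256	23.34	34.46	30.63	26.53	38.38	53.60
TPM1	1650	311	18.85	22.18	26.91	33.88	26.00	25.21
XK	1395	279	20.00	39.43	24.09	30.75	30.39	21.15
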