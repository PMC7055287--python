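pair	s_sites	n_sites	ka	ks	omega	selection	t_mya
CbANK3-CcANK96	371.91	1197.09	0.00	0.02	0.15	purifying	0.11
CaANK25-CaANK24	96.22	320.78	0.28	0.33	0.85	purifying	1.67
CaANK82-CbANK57	130.25	424.76	0.03	0.06	0.54	purifying	0.30
CbANK54-CbANK57	151.41	499.59	0.02	0.02	0.73	purifying	0.12
CaANK36-CbANK28	87.41	293.59	0.02	0.05	0.36	purifying	0.24
CbANK84-CbANK28	88.09	292.91	0.02	0.02	1.05	positive	0.12
CbANK35-CbANK33	69.45	245.55	0.14	0.24	0.60	purifying	1.20
CbANK38-CbANK36	120.81	401.19	1.07	1.16	0.92	purifying	5.87
CaANK77-CaANK38	80.09	306.91	0.03	0.08	0.38	purifying	0.40
CcANK37-CcANK43	100.22	364.78	0.03	0.13	0.21	purifying	0.66
CcANK60-CcANK48	102.73	371.27	0.07	0.14	0.51	purifying	0.70
CaANK45-CaANK47	102.56	386.44	0.01	0.01	0.53	purifying	0.05
CbANK31-CaANK47	102.70	386.31	0.01	0.02	0.26	purifying	0.10
CcANK55-CcANK42	78.25	302.75	0.08	0.11	0.76	purifying	0.55
CaANK50-CcANK40	97.15	361.85	0.08	0.21	0.38	purifying	1.07
CcANK39-CcANK40	87.98	320.02	0.09	0.19	0.46	purifying	0.97
CbANK56-CbANK53	228.17	797.83	0.04	0.09	0.44	purifying	0.45
CbANK8-CaANK10	227.16	714.84	0.01	0.01	0.95	purifying	0.07
CbANK7-CbANK5	287.24	921.76	0.01	0.01	0.93	purifying	0.07
CaANK78-CaANK6	289.95	931.06	0.01	0.01	0.39	purifying	0.07
CbANK11-CbANK6	139.63	481.37	0.03	0.04	0.77	purifying	0.22
CbANK72-CcANK1	65.47	228.53	0.26	1.00	0.27	purifying	5.02
CcANK80-CcANK1	64.38	226.62	0.27	1.03	0.26	purifying	5.20
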