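channel	mni_x	mni_y	mni_z	depth_mm	BA6	BA7	BA40	BA44	BA45	BA46
S1-D1	-40.028	82.122	29.995	26.501	0.00	0.00	0.00	0.00	0.00	9.00
S1-D2	-55.094	68.108	24.682	20.592	0.00	0.00	0.00	2.19	49.95	64.65
S1-D3	-53.044	50.848	42.793	21.260	0.00	0.00	0.00	17.87	5.31	26.36
S2-D2	-69.006	52.147	12.293	19.889	4.95	0.00	0.00	43.55	40.34	0.00
S2-D3	-67.058	34.678	30.363	18.382	46.58	0.00	0.00	36.39	4.39	0.00
S3-D3	-43.666	32.288	59.292	23.451	7.92	0.00	0.00	0.00	0.00	0.00
S3-D4	-10.188	31.269	75.013	24.716	4.50	0.00	0.00	0.00	0.00	0.00
S3-D5	-30.482	11.346	73.230	20.170	17.89	0.00	0.00	0.00	0.00	0.00
S4-D3	-62.067	14.253	48.546	21.681	13.05	0.00	0.00	0.00	0.00	0.00
S4-D5	-49.037	-6.785	62.588	23.176	5.12	0.00	2.89	0.00	0.00	0.00
S4-D6	-64.562	-23.221	46.414	19.983	0.00	0.00	44.54	0.00	0.00	0.00
S5-D6	-72.278	-37.100	25.118	19.872	0.00	0.00	28.81	0.00	0.00	0.00
S6-D5	-31.636	-28.475	71.383	23.443	0.00	17.82	0.66	0.00	0.00	0.00
S6-D6	-47.704	-45.059	55.802	21.682	0.00	18.10	14.22	0.00	0.00	0.00
S6-D7	-11.015	-49.032	71.726	27.577	0.00	2.09	0.00	0.00	0.00	0.00
S6-D8	-28.389	-63.383	55.839	23.815	0.00	15.44	0.00	0.00	0.00	0.00
S7-D6	-58.204	-56.894	34.052	24.029	0.00	16.15	8.89	0.00	0.00	0.00
S7-D8	-38.971	-75.034	34.184	25.066	0.00	15.23	0.00	0.00	0.00	0.00
S8-D7	8.628	-65.081	61.791	32.014	0.00	0.00	0.00	0.00	0.00	0.00
S8-D8	-8.732	-78.971	45.761	25.181	0.00	15.19	0.00	0.00	0.00	0.00
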