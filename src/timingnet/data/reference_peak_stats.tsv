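rat_id	trial_type	peak_time	width50
1	tone	5.93	10.38
2	tone	6.22	12.70
3	tone	4.17	6.87
4	tone	4.02	6.56
5	tone	NA	NA
6	tone	5.04	8.33
7	tone	5.03	7.90
8	tone	4.67	9.83
9	tone	4.60	7.37
10	tone	4.44	14.85
11	tone	3.68	10.80
12	tone	4.06	7.53
13	tone	4.30	7.80
14	tone	4.51	8.39
15	tone	4.99	7.22
16	tone	5.24	10.40
1	flash	21.75	50.19
2	flash	25.14	38.73
3	flash	22.21	37.78
4	flash	27.98	35.94
5	flash	NA	NA
6	flash	26.34	50.34
7	flash	30.68	37.70
8	flash	25.69	43.35
9	flash	26.26	34.27
10	flash	28.86	44.08
11	flash	30.99	43.33
12	flash	25.00	43.56
13	flash	24.06	36.58
14	flash	27.21	32.14
15	flash	25.78	45.97
16	flash	24.22	34.99
1	compound	12.76	45.64
2	compound	19.06	34.81
3	compound	14.8	35.54
4	compound	14.41	34.57
5	compound	NA	NA
6	compound	13.99	33.94
7	compound	12.49	28.17
8	compound	19.12	39.51
9	compound	17.56	36.42
10	compound	17.49	37.93
11	compound	16.14	36.64
12	compound	15.09	39.16
13	compound	15.77	33.54
14	compound	19.39	27.90
15	compound	20.23	38.36
16	compound	14.91	36.32
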