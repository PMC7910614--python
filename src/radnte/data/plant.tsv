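location	time_years	dose_rate_uGy_h	mortality	ref_intercept	ref_slope	ref_fitted
Chernobyl	1	73.6	0.070	4.56	0.28	0.119
Chernobyl	2	52.5	0.172	4.56	0.28	0.141
Chernobyl	3	42.0	0.227	4.56	0.28	0.153
Chernobyl	4	31.5	0.196	4.56	0.28	0.159
Chernobyl	5	21.0	0.166	4.56	0.28	0.162
Chernobyl	6	10.5	0.107	4.56	0.28	0.162
Shepelichi	1	1224.0	0.154	6.74	0.09	0.122
Shepelichi	2	720.0	0.224	6.74	0.09	0.146
Shepelichi	3	648.1	0.218	6.74	0.09	0.159
Shepelichi	4	576.0	0.167	6.74	0.09	0.167
Shepelichi	6	504.0	0.116	6.74	0.09	0.175
Stechanka	1	2.1	0.066	0.74	0.00	0.094
Stechanka	2	2.1	0.100	0.74	0.00	0.102
Stechanka	3	2.1	0.221	0.74	0.00	0.107
Stechanka	4	2.1	0.062	0.74	0.00	0.110
Stechanka	6	2.1	0.074	0.74	0.00	0.113
Tolstyi Les	1	322.5	0.078	6.05	0.26	0.121
Tolstyi Les	2	258.1	0.090	6.05	0.26	0.144
Tolstyi Les	3	193.5	0.138	6.05	0.26	0.157
Tolstyi Les	4	129.0	0.148	6.05	0.26	0.165
Tolstyi Les	6	90.3	0.139	6.05	0.26	0.171
Yanov-6	2	23919.4	0.200	11.13	0.50	0.230
Yanov-6	3	16560.0	0.283	11.13	0.50	0.235
Yanov-6	4	9200.0	0.250	11.13	0.50	0.228
Yanov-6	5	5520.0	0.247	11.13	0.50	0.217
Yanov-8	3	875.0	0.205	6.77	0.00	0.160
Yanov-8	4	875.0	0.111	6.77	0.00	0.168
Yanov-0	1	1288.1	0.125	7.16	0.00	0.123
Yanov-1	1	2208.3	0.104	7.70	0.00	0.124
Yanov-2	1	4415.3	0.180	8.39	0.00	0.128
Yanov-3	1	23919.4	0.131	10.08	0.00	0.156
Yanov-4	1	44159.7	0.141	10.70	0.00	0.184
Yanov-7	2	26680.6	0.216	10.19	0.00	0.203
Damba	5	52.5	0.166	3.96	0.00	0.164
Yanov-10	5	87.5	0.152	4.47	0.00	0.167
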