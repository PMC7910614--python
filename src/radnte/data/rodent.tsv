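location	time_years	dose_rate_uGy_h	mortality	ref_intercept	ref_slope	ref_fitted
Site 2	0	0.0021	0.072	-6.17	0.00	0.022
Site 2	6	0.0021	0.044	-6.17	0.00	0.022
Site 2	5	0.23	0.054	-0.69	0.16	0.054
Site 2	10	0.10	0.114	-0.69	0.16	0.112
Site 3	2	2.42	0.000	1.36	0.28	0.051
Site 3	3	1.85	0.065	1.36	0.28	0.072
Site 3	5	0.75	0.099	1.36	0.28	0.115
Site 3	10	0.27	0.267	1.36	0.28	0.218
Site 4	2	10.23	0.048	2.89	0.24	0.066
Site 4	3	11.07	0.060	2.89	0.24	0.089
Site 4	5	4.32	0.155	2.89	0.24	0.134
Site 4	10	1.81	0.216	2.89	0.24	0.236
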