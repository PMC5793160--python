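index	proposed	wTOM[pcc]	wTOM[sc]	GTOM0[pcc]	GTOM0[sc]	GTOM1[pcc]	GTOM1[sc]	GTOM2[pcc]	GTOM2[sc]	GTOM3[pcc]	GTOM3[sc]
avgDI	3.82e-1	Inf	Inf	Inf	Inf	NA	NA	NA	NA	NA	NA
avgSW	7.82e-2	9.97e-2	3.94e-2	6.55e-2	2.89e-2	NA	NA	NA	NA	NA	NA
avgSC	6.80e-1	4.24e-1	3.41e-1	3.39e-1	3.02e-1	9.41e-2	6.3e-2	1.66e-1	6.53e-2	1.65e-1	6.53e-2
avgCC	2.53e-1	1.52e-1	8.74e-2	1.30e-1	8.64e-2	8.86e-2	5.18e-2	1.47e-1	5.38e-2	1.47e-1	5.38e-2
avgMAR	2.99e-1	1.26e-1	8.24e-2	1.24e-1	1.00e-1	NA	NA	NA	NA	NA	NA
density	2.21e-1	9.83e-2	3.99e-2	6.42e-2	2.90e-2	7.782e-3	3.18e-3	2.40e-2	3.30e-3	2.40e-2	3.30e-3
centralization	1.04e-1	1.36e-1	7.85e-2	1.28e-1	6.83e-2	7.64e-2	4.83e-2	1.24e-1	4.82e-2	1.24e-1	4.82e-2
rand	2.21e-1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
adjusted_rand	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
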