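index	proposed	wTOM[pcc]	wTOM[sc]	GTOM0[pcc]	GTOM0[sc]	GTOM1[pcc]	GTOM1[sc]	GTOM2[pcc]	GTOM2[sc]	GTOM3[pcc]	GTOM3[sc]
avgDI	3.47e-1	Inf	Inf	Inf	Inf	Inf	NA	Inf	NA	Inf	NA
avgSW	1.85e-1	3.13e-1	2.12e-1	9.16e-1	1.61e-1	9.90e-1	NA	9.90e-1	NA	9.90e-1	NA
avgSC	7.41e-1	9.99e-1	6.39e-1	9.77e-1	5.49e-1	9.90e-1	1.08e-1	9.90e-1	1.26e-1	9.90e-1	1.27e-1
avgCC	2.77e-1	9.64e-1	2.76e-1	9.55e-1	2.58e-1	9.90e-1	1.81e-1	9.90e-1	1.98e-1	9.90e-1	1.99e-1
avgMAR	3.25e-1	9.64e-1	2.53e-1	9.52e-1	2.75e-1	NA	NA	NA	NA	NA	NA
density	1.87e-1	9.64e-1	2.11e-1	9.49e-1	1.59e-1	9.80e-1	1.01e-2	9.80e-1	1.12e-2	9.80e-1	1.26e-2
centralization	1.26e-1	1.04e-2	1.21e-1	2.31e-2	1.33e-1	1.01e-2	8.54e-2	1.01e-2	8.80e-2	1.01e-2	8.84e-2
rand	4.29e-1	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
adjusted_rand	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA	NA
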