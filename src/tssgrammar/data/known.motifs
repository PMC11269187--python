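>NRF1	GCGCATGCGC	13.6907
0.050000	0.050000	0.850000	0.050000
0.016667	0.950000	0.016667	0.016667
0.066667	0.066667	0.800000	0.066667
0.010000	0.970000	0.010000	0.010000
0.900000	0.033333	0.033333	0.033333
0.010000	0.010000	0.010000	0.970000
0.083333	0.083333	0.750000	0.083333
0.016667	0.950000	0.016667	0.016667
0.050000	0.050000	0.850000	0.050000
0.033333	0.900000	0.033333	0.033333
>SP1	GGGGCGGGG	12.1806
0.066667	0.066667	0.800000	0.066667
0.016667	0.016667	0.950000	0.016667
0.010000	0.010000	0.970000	0.010000
0.033333	0.033333	0.900000	0.033333
0.050000	0.850000	0.050000	0.050000
0.010000	0.010000	0.970000	0.010000
0.033333	0.033333	0.900000	0.033333
0.066667	0.066667	0.800000	0.066667
0.083333	0.083333	0.750000	0.083333
>NFY	CCAATCA	9.53601
0.050000	0.850000	0.050000	0.050000
0.016667	0.950000	0.016667	0.016667
0.970000	0.010000	0.010000	0.010000
0.970000	0.010000	0.010000	0.010000
0.033333	0.033333	0.033333	0.900000
0.066667	0.800000	0.066667	0.066667
0.750000	0.083333	0.083333	0.083333
>YY1	GCCATNTT	9.5248
0.066667	0.066667	0.800000	0.066667
0.033333	0.900000	0.033333	0.033333
0.010000	0.970000	0.010000	0.010000
0.950000	0.016667	0.016667	0.016667
0.033333	0.033333	0.033333	0.900000
0.250000	0.250000	0.250000	0.250000
0.050000	0.050000	0.050000	0.850000
0.066667	0.066667	0.066667	0.800000
>TATA	TATAWAWR	8.67201
0.033333	0.033333	0.033333	0.900000
0.970000	0.010000	0.010000	0.010000
0.016667	0.016667	0.016667	0.950000
0.970000	0.010000	0.010000	0.010000
0.425000	0.075000	0.075000	0.425000
0.900000	0.033333	0.033333	0.033333
0.400000	0.100000	0.100000	0.400000
0.375000	0.125000	0.375000	0.125000
>ETS	ACAGGAAGTG	13.4349
0.750000	0.083333	0.083333	0.083333
0.050000	0.850000	0.050000	0.050000
0.900000	0.033333	0.033333	0.033333
0.010000	0.010000	0.970000	0.010000
0.010000	0.010000	0.970000	0.010000
0.950000	0.016667	0.016667	0.016667
0.900000	0.033333	0.033333	0.033333
0.050000	0.050000	0.850000	0.050000
0.066667	0.066667	0.066667	0.800000
0.083333	0.083333	0.750000	0.083333
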