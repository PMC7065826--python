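trait	chromosome	qtl	position_cm	intensity	seg_prob_KK	seg_prob_SK	seg_prob_TK	contribution	effect
FlYd	2B	QFlyd.m.tarc-2B	119.72	0.795	0.953	0.099	0.134	0.054	0.790
FlYd	2D	QFlyd.m.tarc-2D	139.57	1.012	0.993	0.663	0.988	0.037	0.554
FlYd	3A	QFlyd.m.tarc-3A	133.00	0.682	0.727	0.674	0.987	0.021	-0.421
FlYd	3B	QFlyd.m.tarc-3B	98.47	1.005	0.993	0.999	0.999	0.065	0.717
FlYd	4D	QFlyd.m.tarc-4D	65.73	1.006	0.996	0.992	0.996	0.044	0.587
FlYd	5A	QFlyd.m.tarc-5A	268.17	1.138	0.447	0.984	0.140	0.050	-0.282
FlYd	5D	QFlyd.m.tarc-5D	261.75	1.178	0.760	0.439	0.955	0.030	0.444
FlYd	6B	QFlyd.m.tarc-6B	127.14	1.012	0.934	0.959	0.996	0.026	0.442
FlYd	6D	QFlyd.m.tarc-6D	111.45	0.578	0.995	0.036	0.144	0.103	0.952
FlYd	7A	QFlyd.m.tarc-7A	145.22	1.008	0.998	0.999	0.998	0.088	0.827
FlYd	7B	QFlyd.m.tarc-7B	59.93	1.090	0.425	0.933	0.267	0.053	0.671
FlYd	7D	QFlyd.m.tarc-7D	179.70	0.985	0.324	0.994	0.983	0.030	-0.497
Fla	1A	QFla.m.tarc-1A	125.00	1.039	0.997	0.057	0.992	0.074	0.066
Fla	2B	QFla.m.tarc-2B	61.13	0.436	0.776	0.083	0.988	0.029	-0.038
Fla	4A	QFla.m.tarc-4A	205.01	1.037	0.954	0.975	0.040	0.036	-0.047
Fla	5D	QFla.m.tarc-5D	79.59	1.027	0.980	0.009	0.997	0.051	-0.050
Fla	6A	QFla.m.tarc-6A	19.14	0.999	0.916	0.047	0.998	0.032	-0.042
Fla	6B	QFla.m.tarc-6B	163.14	0.980	0.995	0.990	0.002	0.029	0.044
Fla	6D	QFla.m.tarc-6D	133.75	0.682	0.988	0.208	0.669	0.028	-0.041
Fla	7A	QFla.m.tarc-7A.1	142.21	1.003	0.999	0.254	0.998	0.081	0.063
Fla	7A	QFla.m.tarc-7A.2	310.39	1.000	0.726	1.000	0.672	0.032	0.041
Fla	7B	QFla.m.tarc-7B.1	50.59	1.016	0.982	0.987	0.532	0.029	-0.039
Fla	7B	QFla.m.tarc-7B.2	229.20	1.000	1.000	1.000	0.950	0.067	0.059
Fla	7D	QFla.m.tarc-7D	39.68	0.631	0.924	0.906	0.964	0.018	-0.030
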