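trait	population	qtl	chromosome	position_cm	intensity	contribution	effect
FlYd	KK	QFlyd.kk.tarc-2D	2D.2	87.6	0.660	0.081	0.794
FlYd	KK	QFlyd.kk.tarc-4D	4D	43.2	0.392	0.064	0.740
FlYd	KK	QFlyd.kk.tarc-7A	7A	136.2	0.900	0.100	0.897
FlYd	SK	QFlyd.sk.tarc-3B	3B.1	72.7	1.001	0.136	0.871
FlYd	SK	QFlyd.sk.tarc-4D	4D	40.9	0.469	0.051	0.535
FlYd	SK	QFlyd.sk.tarc-5A	5A	212.2	1.082	0.086	-0.642
FlYd	SK	QFlyd.sk.tarc-7A	7A	103.9	1.000	0.133	0.860
FlYd	SK	QFlyd.sk.tarc-7B	7B.1	42.1	1.001	0.118	0.826
FlYd	SK	QFlyd.sk.tarc-7D	7D.1	118.7	0.577	0.064	-0.622
FlYd	TK	QFlyd.tk.tarc-2B	2B.2	29.3	0.382	0.050	0.568
FlYd	TK	QFlyd.tk.tarc-2D	2D.2	56.2	0.388	0.059	0.621
FlYd	TK	QFlyd.tk.tarc-3B	3B.1	83.6	0.997	0.092	0.778
FlYd	TK	QFlyd.tk.tarc-4D	4D	114.1	0.992	0.099	0.811
FlYd	TK	QFlyd.tk.tarc-6B	6B	124.4	0.682	0.076	0.691
FlYd	TK	QFlyd.tk.tarc-7A	7A	198.5	0.916	0.085	0.740
Fla	KK	QFla.kk.tarc-1A	1A	96.1	1.001	0.113	0.083
Fla	KK	QFla.kk.tarc-5D	5D	55.2	0.765	0.084	-0.065
Fla	KK	QFla.kk.tarc-7A	7A	125.1	1.004	0.103	0.071
Fla	SK	QFla.sk.tarc-1B	1B.1	34.9	0.499	0.058	-0.045
Fla	SK	QFla.sk.tarc-4A	4A	144.9	0.521	0.075	-0.050
Fla	SK	QFla.sk.tarc-7A	7A	210.6	0.866	0.096	0.058
Fla	SK	QFla.sk.tarc-7B	7B.2	26.0	0.999	0.112	0.060
Fla	TK	QFla.tk.tarc-1A	1A	120.0	0.961	0.103	0.068
Fla	TK	QFla.tk.tarc-7A	7A	159.9	0.859	0.095	0.064
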