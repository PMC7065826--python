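region	chromosome	start_cm	end_cm	start_mb	end_mb	qtls	ideo1	ideo2	ideo3	ideo4	ideo5	ideo6	ideo7	ideo8	ideo9	ideo10
1	1A	116.5	139.1	511.5	528.7	QFla.m.tarc-1A	A	A	A	A	A	A	A	A	A	-
2	2B	56.9	69.3	417.6	652.4	QFla.m.tarc-2B	B	B	-	-	-	-	-	-	-	-
3	2B	114.1	156.0	759.3	776.8	QFlyd.m.tarc-2B	B	B	B	B	B	B	B	B	B	B
4	2D	123.2	152.3	67.2	320.5	QFlyd.m.tarc-2D	B	B	B	B	B	B	B	B	B	B
5	3A	124.3	142.6	595.9	659.6	QFlyd.m.tarc-3A	A	A	A	A	A	A	A	A	A	A
6	3B	90.2	107.4	52.7	431.6	QFlyd.m.tarc-3B	B	B	B	B	B	B	B	B	B	B
7	4A	163.6	230.2	694.9	737.4	QFla.m.tarc-4A	B	B	B	B	B	B	-	-	-	-
8	4D	59.8	74.2	27.2	313.6	QFlyd.m.tarc-4D	B	B	B	B	B	B	B	B	B	B
9	5A	210.2	321.6	584.4	689.9	QFlyd.m.tarc-5A	A	A	A	A	A	A	A	A	A	A
10	5D	68.7	88.2	66.8	365.3	QFla.m.tarc-5D	B	B	B	B	B	B	B	-	-	-
11	5D	313.9	348.7	542.7	558.3	QFlyd.m.tarc-5D	B	B	B	B	B	B	B	B	B	B
12	6A	0.0	65.1	0.6	31.4	QFla.m.tarc-6A	B	B	B	B	-	-	-	-	-	-
13	6B	120.3	133.3	352.1	633.5	QFlyd.m.tarc-6B	B	B	B	B	B	B	B	B	B	B
14	6B	140.9	188.3	645.5	694.1	QFla.m.tarc-6B	A	A	A	-	-	-	-	-	-	-
15	6D	68.4	179.9	23.4	436.9	QFlyd.m.tarc-6D;QFla.m.tarc-6D	B	B	B	B	B	B	B	B	B	B
16	7A	141.1	154.2	127.8	488.7	QFlyd.m.tarc-7A;QFla.m.tarc-7A.1	B	B	B	B	B	B	B	B	B	B
17	7A	298.6	314.7	724.1	733.4	QFla.m.tarc-7A.2	A	A	A	A	A	-	-	-	-	-
18	7B	8.1	64.7	5.9	64.7	QFlyd.m.tarc-7B;QFla.m.tarc-7B.1	B	B	B	B	B	B	B	B	B	B
19	7B	215.3	238.9	706.8	739.4	QFla.m.tarc-7B.2	A	A	A	A	A	A	A	A	-	-
20	7D	9.1	52.8	13.3	32.9	QFla.m.tarc-7D	B	-	-	-	-	-	-	-	-	-
21	7D	129.5	208.0	71.6	530.0	QFlyd.m.tarc-7D	A	A	A	A	A	A	A	A	A	A
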