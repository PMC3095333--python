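# version: 1
# default_threshold: 50.0
pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	4.0000	0.0000	-2.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	-1.0000	-1.0000	-1.0000	-2.0000	-1.0000	-1.0000	-1.0000	1.0000	0.0000	0.0000	-3.0000	-2.0000
2	-1.0000	-4.0000	2.0000	5.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-3.0000	-2.0000	0.0000	-1.0000	2.0000	0.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
3	4.0000	0.0000	-2.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	-1.0000	-1.0000	-1.0000	-2.0000	-1.0000	-1.0000	-1.0000	1.0000	0.0000	0.0000	-3.0000	-2.0000
4	-3.0000	-2.0000	-4.0000	-3.0000	1.0000	-2.0000	-2.0000	-3.0000	-3.0000	-2.0000	-1.0000	-4.0000	-4.0000	-2.0000	-3.0000	-3.0000	-2.0000	-3.0000	11.0000	2.0000
5	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
6	-2.0000	-3.0000	1.0000	0.0000	-3.0000	0.0000	1.0000	-3.0000	0.0000	-3.0000	-2.0000	6.0000	-2.0000	0.0000	0.0000	1.0000	0.0000	-3.0000	-4.0000	-2.0000
7	-1.0000	-1.0000	-4.0000	-3.0000	0.0000	-4.0000	-3.0000	2.0000	-2.0000	4.0000	2.0000	-3.0000	-3.0000	-2.0000	-2.0000	-2.0000	-1.0000	1.0000	-2.0000	-1.0000
8	0.0000	-3.0000	-1.0000	-2.0000	-3.0000	6.0000	-2.0000	-4.0000	-2.0000	-4.0000	-3.0000	0.0000	-2.0000	-2.0000	-2.0000	0.0000	-2.0000	-3.0000	-2.0000	-3.0000
9	-2.0000	-3.0000	1.0000	0.0000	-3.0000	0.0000	1.0000	-3.0000	0.0000	-3.0000	-2.0000	6.0000	-2.0000	0.0000	0.0000	1.0000	0.0000	-3.0000	-4.0000	-2.0000
10	4.0000	0.0000	-2.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	-1.0000	-1.0000	-1.0000	-2.0000	-1.0000	-1.0000	-1.0000	1.0000	0.0000	0.0000	-3.0000	-2.0000
11	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
12	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
13	-1.0000	-3.0000	-1.0000	1.0000	-3.0000	-2.0000	-1.0000	-3.0000	5.0000	-2.0000	-1.0000	0.0000	-1.0000	1.0000	2.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
14	-1.0000	-3.0000	0.0000	2.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-2.0000	0.0000	0.0000	-1.0000	5.0000	1.0000	0.0000	-1.0000	-2.0000	-2.0000	-1.0000
15	0.0000	-3.0000	-1.0000	-2.0000	-3.0000	6.0000	-2.0000	-4.0000	-2.0000	-4.0000	-3.0000	0.0000	-2.0000	-2.0000	-2.0000	0.0000	-2.0000	-3.0000	-2.0000	-3.0000
16	-2.0000	-3.0000	6.0000	2.0000	-3.0000	-1.0000	-1.0000	-3.0000	-1.0000	-4.0000	-3.0000	1.0000	-1.0000	0.0000	-2.0000	0.0000	-1.0000	-3.0000	-4.0000	-3.0000
17	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
18	-2.0000	-3.0000	6.0000	2.0000	-3.0000	-1.0000	-1.0000	-3.0000	-1.0000	-4.0000	-3.0000	1.0000	-1.0000	0.0000	-2.0000	0.0000	-1.0000	-3.0000	-4.0000	-3.0000
19	-1.0000	-4.0000	2.0000	5.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-3.0000	-2.0000	0.0000	-1.0000	2.0000	0.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
20	4.0000	0.0000	-2.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	-1.0000	-1.0000	-1.0000	-2.0000	-1.0000	-1.0000	-1.0000	1.0000	0.0000	0.0000	-3.0000	-2.0000
21	-1.0000	-1.0000	-3.0000	-3.0000	0.0000	-4.0000	-3.0000	4.0000	-3.0000	2.0000	1.0000	-3.0000	-3.0000	-3.0000	-3.0000	-2.0000	-1.0000	3.0000	-3.0000	-1.0000
22	-1.0000	-4.0000	2.0000	5.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-3.0000	-2.0000	0.0000	-1.0000	2.0000	0.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
23	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
24	-2.0000	-2.0000	-3.0000	-2.0000	3.0000	-3.0000	2.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-3.0000	-1.0000	-2.0000	-2.0000	-2.0000	-1.0000	2.0000	7.0000
25	-1.0000	-3.0000	0.0000	2.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-2.0000	0.0000	0.0000	-1.0000	5.0000	1.0000	0.0000	-1.0000	-2.0000	-2.0000	-1.0000
26	-1.0000	-3.0000	-1.0000	1.0000	-3.0000	-2.0000	-1.0000	-3.0000	5.0000	-2.0000	-1.0000	0.0000	-1.0000	1.0000	2.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
27	4.0000	0.0000	-2.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	-1.0000	-1.0000	-1.0000	-2.0000	-1.0000	-1.0000	-1.0000	1.0000	0.0000	0.0000	-3.0000	-2.0000
28	-1.0000	-1.0000	-4.0000	-3.0000	0.0000	-4.0000	-3.0000	2.0000	-2.0000	4.0000	2.0000	-3.0000	-3.0000	-2.0000	-2.0000	-2.0000	-1.0000	1.0000	-2.0000	-1.0000
29	-1.0000	-4.0000	2.0000	5.0000	-3.0000	-2.0000	0.0000	-3.0000	1.0000	-3.0000	-2.0000	0.0000	-1.0000	2.0000	0.0000	0.0000	-1.0000	-2.0000	-3.0000	-2.0000
30	-1.0000	-1.0000	-4.0000	-3.0000	0.0000	-4.0000	-3.0000	2.0000	-2.0000	4.0000	2.0000	-3.0000	-3.0000	-2.0000	-2.0000	-2.0000	-1.0000	1.0000	-2.0000	-1.0000
31	-2.0000	-3.0000	6.0000	2.0000	-3.0000	-1.0000	-1.0000	-3.0000	-1.0000	-4.0000	-3.0000	1.0000	-1.0000	0.0000	-2.0000	0.0000	-1.0000	-3.0000	-4.0000	-3.0000
32	-1.0000	-3.0000	-1.0000	-1.0000	-4.0000	-2.0000	-2.0000	-3.0000	-1.0000	-3.0000	-2.0000	-2.0000	7.0000	-1.0000	-2.0000	-1.0000	-1.0000	-2.0000	-4.0000	-3.0000
33	-1.0000	-3.0000	-2.0000	0.0000	-3.0000	-2.0000	0.0000	-3.0000	2.0000	-2.0000	-1.0000	0.0000	-2.0000	1.0000	5.0000	-1.0000	-1.0000	-3.0000	-3.0000	-2.0000
34	1.0000	-1.0000	0.0000	0.0000	-2.0000	0.0000	-1.0000	-2.0000	0.0000	-2.0000	-1.0000	1.0000	-1.0000	0.0000	-1.0000	4.0000	1.0000	-2.0000	-3.0000	-2.0000
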