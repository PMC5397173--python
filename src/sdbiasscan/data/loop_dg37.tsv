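# Loop length penalties, dG37 kcal/mol (Turner 2004 initiation terms).
# size 1..30; hairpin undefined below size 3, internal below size 2.
size	hairpin	bulge	internal
1		3.80	
2		2.80	1.00
3	5.40	3.20	1.00
4	5.60	3.60	1.10
5	5.70	4.00	2.00
6	5.40	4.40	2.00
7	6.00	4.60	2.10
8	5.50	4.70	2.30
9	6.40	4.80	2.40
10	6.50	4.90	2.50
11	6.60	5.00	2.60
12	6.70	5.10	2.70
13	6.80	5.20	2.80
14	6.90	5.30	2.90
15	6.90	5.40	2.90
16	7.00	5.40	3.00
17	7.10	5.50	3.10
18	7.10	5.50	3.10
19	7.20	5.60	3.20
20	7.20	5.70	3.30
21	7.30	5.70	3.30
22	7.30	5.80	3.40
23	7.40	5.80	3.40
24	7.40	5.80	3.50
25	7.50	5.90	3.50
26	7.50	5.90	3.50
27	7.50	6.00	3.60
28	7.60	6.00	3.60
29	7.60	6.00	3.70
30	7.70	6.10	3.70
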