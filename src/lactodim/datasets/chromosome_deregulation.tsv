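chromosome	n_deregulated	delta_percent
19	12	0.80
3	10	0.77
2	12	0.75
5	8	0.73
13	3	0.60
9	6	0.60
8	5	0.59
16	6	0.59
7	7	0.58
1	13	0.57
11	8	0.53
4	5	0.53
6	6	0.44
14	4	0.42
21	1	0.33
18	1	0.29
20	2	0.29
17	3	0.22
12	2	0.17
22	1	0.15
15	1	0.13
10	1	0.10
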