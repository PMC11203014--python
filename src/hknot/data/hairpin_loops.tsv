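length	dG
3	5.4
4	5.6
5	5.7
6	5.8
7	5.9
8	6.0
9	6.1
10	6.2
11	6.3
12	6.4
13	6.5
14	6.6
15	6.7
16	6.8
17	6.9
18	7.0
19	7.1
20	7.2
21	7.3
22	7.4
23	7.5
24	7.6
25	7.7
26	7.8
27	7.9
28	8.0
29	8.1
30	8.2
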