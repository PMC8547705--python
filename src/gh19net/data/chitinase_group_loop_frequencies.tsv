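group	loop_1	loop_2	loop_3	loop_4	loop_5	loop_C
1	88.2	93.1	88.7	97.8	96.7	91.8
2	95.4	0	99.8	5.6	0	0
3	90.5	95.5	97.0	100	99.8	94.5
4	96.8	96.8	100	100	0	71.0
5	0	0	99.9	99.8	0	0
6	0	99.1	99.1	99.7	99.6	98.0
7	0	0	0	100	100	93.3
8	0	97.0	98.5	100	98.5	76.5
9	0	100	100	100	100	78.6
10	0	100	100	100	100	15.1
11	17.9	53.6	100	78.6	60.7	42.9
12	93.0	100	100	100	100	100
13	0	0	100	73.3	0	66.7
14	0	30	60	88.9	0	0
15	0	0	100	22.2	0	0
16	0	0	95.6	98.5	0	0
17	19.6	0	100	97.8	0	0
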