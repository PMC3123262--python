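No	Test	Ref	Type	Events
1	F1	F1	Self1	13
2	H1	F1	High1	13
3	L1	F1	Low1	7
4	F2	F2	Self2	8
5	H2	F2	High2	7
6	L2	F2	Low2	57
7	F3	F3	Self3	39
8	H3	F3	High3	17
9	L3	F3	Low3	22
10	Dt	Dt	Self4	3
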