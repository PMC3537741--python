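group	A	C	D	M	N	S	Sb	Sl	Ss	Ssh	T	U	Lophopyrum	Crithopsis	Dasypyrum
1	0	0	1	P	0	1	1	1	1	1	0	P	1	1	1
2	0	0	1	0	0	1	1	1	1	1	1	0	1	0	0
3	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
4	1	0	0	1	1	0	0	0	0	0	0	0	0	0	P
5	0	0	0	0	0	0	1:9cys	1:9cys	1:9cys	1:9cys	0	0	0	0	0
6	0	1:9cys	1:9cys	1:9cys	1:9cys	1:9cys	0	0	0	0	1:9cys	1:9cys	1	0	0
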