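# PAH mutations: residual enzyme activity (% of wildtype) and score
# (catalytic domain 143-410).
label	activity	score
Y414C	28	0.112
R241C	25	0.136
A403V	32	0.125
R261Q	30	0.071
E390G	75	0.086
R68S	98	0.157
I65T	29	0.153
V245A	50	0.126
L48S	39	0.247
F39L	96	0.136
D415N	72	0.072
A395P	15	0.139
A104D	26	0.091
R408Q	55	0.063
P211T	72	0.185
V388M	43	0.15
R241H	23	0.131
I306V	39	0.161
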