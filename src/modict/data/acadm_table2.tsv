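# ACADM mutation pairs: residual enzyme activity (% of wildtype) and score.
# Pair scores are the average of the two mutations' individual scores.
label	activity	score
K329E/I78T	0	46.5
K329E/M328V	0	59.5
K329E/D345Y	3	57
K329E/M155T	3	51
K329E/K329E	5	53
K329E/L409F	6	56.5
Y337S/Y337S	8	56
G267R/G267R	15	55
K329E/R206C	12.5	59.5
M326T/I233T	15	57
G267R/K178T	20	48
G267R/Y67H	30	47.5
K329E/Y67H	35	46.5
K329E/E43K	60	53.5
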