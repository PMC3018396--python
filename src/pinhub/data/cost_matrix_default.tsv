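# Default misclassification cost matrix for hub-role decisions.
# Rows = true class, columns = predicted class, order NH IC PH DH.
# Mistaking a true hub (PH/DH) for NH/IC costs 0.9; confusions among
# non-hub classes or among hub classes cost 0.1-0.2; correct = 0.
0	0.1	0.2	0.2
0.1	0	0.2	0.2
0.9	0.9	0	0.2
0.9	0.9	0.2	0
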