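phase,index,days
I,1,0.57014
I,2,0.07431
I,3,0.15278
I,4,0.14583
I,5,0.13889
I,6,0.14931
I,7,0.03333
I,8,0.08681
I,9,0.33681
I,10,0.03819
I,11,0.24653
I,12,0.29514
I,13,0.11944
I,14,0.05208
I,15,0.12500
I,16,0.25000
I,17,0.40069
I,18,0.02500
I,19,0.12014
I,20,0.11458
I,21,0.00347
I,22,0.12014
I,23,0.04861
I,24,0.02778
I,25,0.32639
I,26,0.64931
I,27,0.14931
I,28,0.01389
I,29,0.03819
I,30,0.46806
I,31,0.22222
I,32,0.29514
I,33,0.53472
I,34,0.15139
I,35,0.52569
I,36,0.07986
I,37,0.27083
I,38,0.04514
I,39,0.13542
I,40,0.08681
I,41,0.40347
I,42,0.12639
I,43,0.18403
I,44,0.70833
I,45,0.15625
I,46,0.24653
I,47,0.04514
I,48,0.01736
I,49,1.08889
I,50,0.05208
I,51,0.02778
I,52,0.03472
I,53,0.23611
I,54,0.35972
II,1,0.38231
II,2,0.44270
II,3,0.28831
II,4,0.18758
II,5,0.09674
II,6,0.20090
II,7,0.57208
II,8,0.49713
II,9,0.13790
II,10,0.31507
II,11,0.74995
II,12,0.09923
II,13,0.49534
II,14,0.68715
II,15,0.24903
II,16,0.22786
II,17,0.13581
II,18,0.63413
II,19,0.30506
II,20,0.25665
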