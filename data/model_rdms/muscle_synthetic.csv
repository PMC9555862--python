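,T,I,M,R,P
T,0.0,5.65,7.6925,8.895,9.0425
I,5.65,0.0,3.5225,4.515,5.1525
M,7.6925,3.5225,0.0,0.1475,0.53
R,8.895,4.515,0.1475,0.0,0.1475
P,9.0425,5.1525,0.53,0.1475,0.0
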