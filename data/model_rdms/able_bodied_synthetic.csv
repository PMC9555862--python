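,T,I,M,R,P
T,0.0,1.49,2.96,5.41,8.84
I,1.49,0.0,0.49,1.96,4.41
M,2.96,0.49,0.0,0.49,1.96
R,5.41,1.96,0.49,0.0,0.49
P,8.84,4.41,1.96,0.49,0.0
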