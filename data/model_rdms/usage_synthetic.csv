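,T,I,M,R,P
T,0.0,5.2225,7.15,8.3594,8.49
I,5.2225,0.0,3.4625,4.5099,5.1525
M,7.15,3.4625,0.0,0.1174,0.42
R,8.3594,4.5099,0.1174,0.0,0.1274
P,8.49,5.1525,0.42,0.1274,0.0
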