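scenario_id,device,wire_count,deployment,l_c,q_c
1,PED,48,nominal,66.8,170
2,PED,48,nominal,114,464
3,PED,48,nominal,137,133
4,PED,48,nominal,135,131
5,PED,48,oversized,5.6,239
6,PED,48,oversized,4.3,281
7,PED,48,oversized,4.7,267
8,PED,48,oversized,42.8,157
9,P64,64,nominal,186,139
10,P64,64,nominal,164,187
11,P64,64,nominal,160,349
12,P64,64,oversized,5.8,316
13,P64,64,oversized,19.3,232
14,P64,64,oversized,6.3,308
15,P64,64,oversized,9.5,243
16,P64,64,oversized,36.1,204
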