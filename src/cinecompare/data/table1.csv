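patient,observer1,observer2,average,automated
1,0.6,0.6,0.6,0.4
2,0.8,1,0.9,1
3,0,0,0,0.4
4,0.6,0.6,0.6,1
5,0.2,0.8,0.5,0
6,0.6,1,0.8,0.4
7,1,1,1,0.6
8,0.2,0.6,0.4,0.4
9,0.8,1,0.9,1
10,0.8,0.8,0.8,0.4
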