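patient,method,highest_intensity,cluster1,cluster2,cluster3
1,SPM,D,C,PC,PC
2,SPM,C,C,C,PC
3,SPM,C,C,C,D
4,SPM,C,C,C,C
5,SPM,C,C,D,PC
6,SPM,D,C,D,C
7,SPM,D,D,D,C
8,SPM,D,C,D,D
9,SPM,D,D,PC,D
10,SPM,D,D,D,D
11,SPM,PC,C,D,D
12,SPM,C,C,C,PC
13,SPM,C,C,D,D
14,SPM,D,D,D,D
15,SPM,D,C,D,D
16,SPM,PC,C,D,D
17,SPM,D,D,D,D
18,SPM,D,D,D,PC
19,SPM,D,C,D,D
20,SPM,C,C,D,D
1,Analyze,C,C,C,D
2,Analyze,D,D,C,D
3,Analyze,C,C,D,C
4,Analyze,C,C,D,D
5,Analyze,C,C,D,C
6,Analyze,D,D,D,C
7,Analyze,PC,D,D,PC
8,Analyze,C,C,D,D
9,Analyze,C,C,C,D
10,Analyze,C,C,D,D
11,Analyze,C,C,C,D
12,Analyze,C,C,C,D
13,Analyze,C,C,D,D
14,Analyze,C,C,D,D
15,Analyze,C,C,D,D
16,Analyze,C,C,C,PC
17,Analyze,D,D,D,D
18,Analyze,D,D,D,PC
19,Analyze,C,C,D,D
20,Analyze,D,D,D,C
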