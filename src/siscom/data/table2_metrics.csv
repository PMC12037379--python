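patient,method,highest_intensity,n_clusters,vol1_mm3,vol2_mm3,vol3_mm3
1,SPM,3.46,9,803.0,304.6,110.8
2,SPM,3.70,16,494.0,125.0,82.0
3,SPM,4.63,6,8566.0,3.0,3.0
4,SPM,4.75,7,22522.7,3.5,0.8
5,SPM,5.12,6,17191.1,1160.0,100.0
6,SPM,2.92,4,17816.9,7610.0,6712.0
7,SPM,3.32,8,20311.0,11723.0,3116.0
8,SPM,3.63,12,54264.1,6893.0,1360.0
9,SPM,3.55,11,29354.9,2246.0,1189.0
10,SPM,3.10,13,9906.0,6887.0,4344.0
11,SPM,4.79,6,55616.5,3021.0,1069.0
12,SPM,2.64,6,24269.2,7.0,6.0
13,SPM,3.48,56,48057.0,1835.0,1576.0
14,SPM,3.72,14,11163.0,7469.0,2450.0
15,SPM,3.48,44,42538.1,4546.9,3983.9
16,SPM,3.83,10,29206.1,3377.0,1071.0
17,SPM,2.87,25,5531.0,3663.0,1610.0
18,SPM,2.68,6,8464.9,3552.0,1837.0
19,SPM,3.71,57,20035.1,17460.1,544.0
20,SPM,3.94,8,11002.0,6559.0,3659.0
1,Analyze,249,79,18157.5,10283.6,3618.0
2,Analyze,250,88,6048.0,4704.8,3675.4
3,Analyze,254,120,15990.8,4363.9,3125.3
4,Analyze,252,23,58276.1,1420.9,948.4
5,Analyze,254,95,43173.0,8339.6,2322.0
6,Analyze,255,12,30240.0,13864.5,9072.0
7,Analyze,251,48,16544.3,12693.4,11724.8
8,Analyze,253,21,63723.4,14738.6,4765.5
9,Analyze,254,30,25882.9,6183.0,2298.4
10,Analyze,254,86,13510.1,8066.3,3688.9
11,Analyze,254,31,43135.9,3705.8,2862.0
12,Analyze,254,21,24094.1,7435.1,1022.6
13,Analyze,254,44,26038.1,16166.3,6584.6
14,Analyze,255,95,16048.1,9510.8,4475.3
15,Analyze,255,63,40516.9,6179.6,2912.6
16,Analyze,255,93,11623.5,10543.5,5194.1
17,Analyze,247,66,22086.0,5531.6,3344.6
18,Analyze,245,52,11326.5,6162.8,4998.4
19,Analyze,254,41,26044.9,16186.5,6588.0
20,Analyze,252,67,9976.5,8046.0,3483.0
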