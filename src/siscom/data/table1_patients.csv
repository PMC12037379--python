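patient,age,gender,gold_standard_side,gold_standard_lobe,pathology,engel
1,51,Female,left,temporal,Left hippocampal sclerosis,I-A
2,53,Female,left,temporal,Left hippocampal sclerosis,I-A
3,37,Female,left,temporal,Left hippocampal sclerosis,I-A
4,50,Female,left,temporal,Left hippocampal sclerosis,I-A
5,10,Female,left,temporal,Left hippocampal sclerosis,I-A
6,52,Male,right,temporal,Right hippocampal sclerosis,I-D
7,44,Male,right,temporal,Right hippocampal sclerosis,I-A
8,51,Male,left,temporal,Left hippocampal sclerosis,II-A
9,58,Male,right,temporal,Right hippocampal sclerosis,I-A
10,28,Male,left,temporal,Left hippocampal sclerosis,I-A
11,52,Female,left,temporal,Left hippocampal sclerosis,I-B
12,27,Female,left,temporal,Left hippocampal sclerosis,I-A
13,40,Male,right,temporal,Right hippocampal sclerosis,I-C
14,34,Female,left,temporal,Left hippocampal sclerosis,I-A
15,51,Male,left,temporal,CA1 fibrillary gliosis,I-B
16,42,Female,left,temporal,Ganglioglioma,I-D
17,45,Female,right,temporal,Focal cortical dysplasia IB,I-A
18,57,Male,left,temporal,Left hippocampal sclerosis,II-A
19,29,Male,right,temporal,Astrogliosis,I-A
20,39,Female,left,temporal,Left hippocampal sclerosis,I-D
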