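patient_id,size_class,state,dp_mmhg,nfd
1,smaller,rest,14,0.12
1,smaller,stress,23,0.13
1,reference,rest,12,0.12
1,reference,stress,18,0.12
1,larger,rest,9,0.10
1,larger,stress,14,0.09
2,smaller,rest,13,0.21
2,smaller,stress,19,0.20
2,reference,rest,10,0.19
2,reference,stress,18,0.20
2,larger,rest,9,0.19
2,larger,stress,13,0.18
3,smaller,rest,19,0.14
3,smaller,stress,29,0.14
3,reference,rest,16,0.12
3,reference,stress,25,0.14
3,larger,rest,14,0.13
3,larger,stress,23,0.14
4,smaller,rest,36,0.12
4,smaller,stress,55,0.12
4,reference,rest,29,0.13
4,reference,stress,44,0.13
4,larger,rest,23,0.12
4,larger,stress,36,0.12
5,smaller,rest,14,0.12
5,smaller,stress,21,0.13
5,reference,rest,10,0.10
5,reference,stress,16,0.11
5,larger,rest,8,0.09
5,larger,stress,12,0.10
6,smaller,rest,8,0.04
6,smaller,stress,12,0.04
6,reference,rest,7,0.05
6,reference,stress,10,0.03
6,larger,rest,6,0.04
6,larger,stress,9,0.04
7,smaller,rest,21,0.12
7,smaller,stress,31,0.12
7,reference,rest,16,0.12
7,reference,stress,25,0.12
7,larger,rest,13,0.12
7,larger,stress,19,0.12
8,smaller,rest,14,0.08
8,smaller,stress,23,0.08
8,reference,rest,10,0.08
8,reference,stress,16,0.09
8,larger,rest,8,0.07
8,larger,stress,13,0.06
9,smaller,rest,14,0.14
9,smaller,stress,21,0.15
9,reference,rest,12,0.14
9,reference,stress,18,0.14
9,larger,rest,9,0.13
9,larger,stress,14,0.12
10,smaller,rest,21,0.13
10,smaller,stress,31,0.13
10,reference,rest,16,0.13
10,reference,stress,25,0.13
10,larger,rest,14,0.12
10,larger,stress,21,0.12
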