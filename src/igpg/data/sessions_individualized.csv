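subject_id,session,spo2_before,spo2_after,hr_before,hr_after
1,individualized,97,95,80,74
2,individualized,96,96,90,105
3,individualized,97,96,107,113
4,individualized,97,98,103,113
5,individualized,98,97,83,87
6,individualized,98,97,75,84
7,individualized,99,98,80,88
8,individualized,98,96,79,83
9,individualized,98,98,78,79
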