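subject_id,session,spo2_before,spo2_after,hr_before,hr_after
1,general,96,91,80,88
2,general,97,96,82,104
3,general,98,96,105,120
4,general,97,96,96,109
5,general,97,95,82,89
6,general,98,97,77,89
7,general,99,96,82,91
8,general,98,94,76,89
9,general,98,96,81,79
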