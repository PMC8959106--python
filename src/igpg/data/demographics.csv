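subject,age,gender,height_cm,weight_kg,paretic_side,fac,diagnosis
1,42,Male,174,77,Left,IV,The cerebral thrombosis
2,40,Male,170,63,Left,IV,The putamen hemorrhage
3,47,Male,160,58,Right,III,The putamen hemorrhage
4,56,Female,153,51,Right,IV,The putamen hemorrhage
5,65,Male,169,90,Left,III,The cerebral thrombosis
6,40,Male,166,72,Left,IV,The cerebral thrombosis
7,33,Male,165,85,Right,III,The putamen hemorrhage
8,69,Male,165,70,Right,III,The putamen hemorrhage
9,42,Male,168,75,Left,IV,The cerebral thrombosis
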