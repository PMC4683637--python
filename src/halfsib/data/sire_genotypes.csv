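sample,MaMS8_a,MaMS8_b,Sev5_a,Sev5_b,Mfav4_a,Mfav4_b,Mfav6_a,Mfav6_b,Mfav7_a,Mfav7_b,Sev8_a,Sev8_b
A,200,200,280,322,379,379,391,391,453,465,190,196
B,200,203,292,322,379,379,389,391,471,486,187,190
C,200,200,283,313,375,375,419,429,453,471,190,193
D,197,200,301,322,375,379,423,423,465,486,190,196
E,200,200,283,316,375,391,389,389,453,474,190,193
F,197,197,307,313,375,375,391,391,462,471,190,202
G,197,200,301,328,379,379,391,391,474,474,193,205
H,197,200,280,307,383,383,389,389,453,453,190,193
J,197,200,280,313,379,379,389,389,477,498,193,193
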