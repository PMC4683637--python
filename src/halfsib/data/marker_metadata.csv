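locus,size_min,size_max,n_alleles,dye
Mfav4,375,391,5,FAM
Sev5,280,328,20,FAM
MaMS8,197,203,3,FAM
Mfav6,387,429,11,HEX
Mfav7,453,498,9,HEX
Sev8,187,205,10,NED
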