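frame_time,chain,residue,icode,code
0.0000,A,200,,C
0.0000,A,201,,C
0.0000,A,202,,C
0.0000,A,203,,E
0.0000,A,204,,E
0.0000,A,205,,E
0.0000,A,206,,E
0.0000,A,207,,E
0.0000,A,208,,E
0.0000,A,209,,C
0.0000,A,210,,C
0.0000,A,211,,C
0.0000,A,212,,C
0.0000,D,204,,C
0.0000,D,205,,E
0.0000,D,206,,E
0.0000,D,207,,E
0.0000,D,208,,E
0.0000,D,209,,E
0.0000,D,210,,E
0.0000,A,,,beta_fraction=46.15
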