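frame_time,descriptor,value,unit,input
0.0000,d_nTM2_nTM10,1.2728,nm,bundle.pdb
0.0000,d_nTM5_nTM7,1.2728,nm,bundle.pdb
0.0000,d_nTM2_nTM7,1.8000,nm,bundle.pdb
0.0000,theta_TM2,89.43,degree,bundle.pdb
0.0000,theta_TM7,89.83,degree,bundle.pdb
0.0000,pore_ring_radius,0.9267,nm,bundle.pdb
0.0000,d_mTM2_mTM4,,,bundle.pdb
0.0000,IS1,,,bundle.pdb
0.0000,IS2,,,bundle.pdb
0.0000,IS3,,,bundle.pdb
0.0000,IS4,,,bundle.pdb
0.0000,theta_plug,,,bundle.pdb
0.0000,theta_cTM4nTM1,,,bundle.pdb
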