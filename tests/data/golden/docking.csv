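substrate,group,n_poses,n_contacting,percentage
anchorlike,SRP_dependent,30,16,53.33
signal-like,SRP_independent,30,5,16.67
__enrichment__,SRP_dependent,30,16,0.00305361
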