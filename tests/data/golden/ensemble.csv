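quantity,value
mean_bound,1.8789
se_bound,0.0086
mean_free,1.7207
se_free,0.0080
N,10
K,5
n,5
k,5
p_upper,0.00396825
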