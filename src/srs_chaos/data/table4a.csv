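block,true_class,n_parts,snore,breathing,silence,sensitivity_pct,ppv_pct,total_accuracy_pct
training,snore,1260,1190,10,60,94.44,100,92.79
training,breathing,746,0,546,200,73.19,94.63,
training,silence,2031,0,21,2010,98.97,88.55,
test,snore,1175,1075,42,58,91.49,97.64,91.61
test,breathing,746,10,457,279,61.26,85.74,
test,silence,3313,16,34,3263,98.49,90.64,
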