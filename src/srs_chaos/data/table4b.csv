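block,true_class,n_parts,snore,breathing,silence,sensitivity_pct,ppv_pct,total_accuracy_pct
training,snore,1260,1150,91,19,91.26,96.88,86.97
training,breathing,746,32,597,117,80.02,62.84,
training,silence,2031,5,262,1764,86.86,92.84,
test,snore,1175,932,202,41,79.31,94.81,86.75
test,breathing,746,35,426,285,57.10,57.41,
test,silence,3313,16,114,3183,96.07,90.70,
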