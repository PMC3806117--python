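block,true_class,n_parts,snore,breathing,silence,sensitivity_pct,ppv_pct,total_accuracy_pct
training,snore,1156,971,162,23,83.99,96.14,84.61
training,breathing,721,39,423,259,58.67,69.00,
training,silence,1445,0,28,1417,98.06,83.40,
test,snore,1280,938,303,39,73.28,87.91,80.55
test,breathing,772,128,414,230,53.62,50.79,
test,silence,2058,1,98,1959,95.19,87.92,
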