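block,true_class,n_parts,snore,breathing,silence,sensitivity_pct,ppv_pct,total_accuracy_pct
training,snore,1156,1097,42,17,94.90,96.65,90.07
training,breathing,721,32,525,164,72.82,82.55,
training,silence,1445,6,69,1370,94.81,88.33,
test,snore,1280,1121,135,24,87.58,85.57,84.65
test,breathing,772,175,523,74,67.75,60.32,
test,silence,2058,14,209,1835,89.16,94.93,
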