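subject,phase,snore,breathing,silence
1,train,25,23,16
2,train,15,15,15
3,train,15,15,15
4,train,15,15,15
5,train,25,25,8
6,train,39,25,11
7,train,25,15,25
8,train,25,25,25
9,train,25,15,25
10,train,25,25,10
11,train,0,10,7
12,train,25,25,8
1,test,25,23,15
2,test,15,15,15
3,test,15,15,15
4,test,15,15,15
5,test,25,25,8
6,test,39,25,10
7,test,25,15,25
8,test,25,25,25
9,test,25,15,25
10,test,25,25,10
11,test,0,10,6
12,test,25,25,7
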