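subject,side,snore,breathing,silence
2,train,30,30,30
3,train,30,30,30
4,train,30,30,30
9,train,50,30,50
10,train,50,50,20
11,train,0,20,13
1,test,50,46,31
5,test,50,50,16
6,test,78,50,21
7,test,50,30,50
8,test,50,50,50
12,test,50,50,15
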