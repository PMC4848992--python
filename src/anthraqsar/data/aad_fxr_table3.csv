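id,structure,ec50_uM,pec50,split,pred_mlr,pred_comfa
1,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(C(=O)O)c2)cc1,0.28,6.553,train,6.784,6.704
2,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc(C(F)(F)F)cc2)c1,6.9,5.161,test,5.653,5.171
3,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc(Br)cc2)c1,3.7,5.432,train,5.451,5.485
4,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc3c(c2)OCO3)c1,10,5.0,train,5.336,5.133
5,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc3c(c2)OCCO3)c1,4.9,5.31,test,5.714,5.133
6,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc(C(F)(F)F)c(F)c2)c1,5,5.301,train,5.232,5.358
7,O=C(O)c1cccc(NC(=O)c2ccccc2S/C=C/c2ccccc2)c1,5.2,5.284,test,4.85,5.639
8,CC(=O)c1cccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)c1,0.48,6.319,train,6.592,6.775
9,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(C#N)c2)cc1,0.23,6.638,train,6.619,6.506
10,COc1cccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)c1,0.38,6.42,train,6.661,6.327
11,CSc1cccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)c1,0.2,6.699,train,6.616,6.655
12,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(-c3nnn[nH]3)c2)cc1,2.9,5.538,train,5.854,5.695
13,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(C(N)=O)c2)cc1,0.074,7.131,train,7.203,7.099
14,COc1ccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)cc1OC,0.071,7.149,test,7.771,6.606
15,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(CC(=O)O)c2)cc1,0.42,6.377,train,6.493,6.414
16,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cccc(CCC(=O)O)c2)cc1,0.064,7.194,train,7.143,6.999
17,Cc1c(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)cccc1C(=O)O,0.042,7.377,train,7.115,7.266
18,COc1ccc(C(=O)O)cc1NC(=O)c1ccccc1Sc1ccc(C(C)(C)C)cc1,4.7,5.328,train,5.307,5.444
19,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cc(C(=O)O)ccc2F)cc1,0.48,6.319,train,6.148,6.361
20,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2cc(C(=O)O)ccc2Cl)cc1,1.1,5.959,test,6.569,5.759
21,Cc1ccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)cc1C(=O)O,0.045,7.347,train,7.209,6.934
22,COc1ccc(NC(=O)c2ccccc2Sc2ccc(C(C)(C)C)cc2)cc1C(=O)O,0.047,7.328,test,7.65,7.563
23,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2ccc(Cl)c(C(=O)O)c2)cc1,0.28,6.553,train,6.845,6.931
24,CC(C)(C)c1ccc(Sc2ccccc2C(=O)Nc2ccc(Br)c(C(=O)O)c2)cc1,0.15,6.824,train,6.937,6.889
25,CC(C)(C)c1ccc(Sc2ccc(Cl)cc2C(=O)Nc2cccc(C(=O)O)c2)cc1,0.047,7.328,train,6.862,6.868
26,O=C(O)Cc1ccc(NC(=O)c2ccccc2Sc2ccc3ccccc3c2)cc1,3.1,5.509,test,5.492,5.082
27,Cc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2ccc(C)c(C(=O)O)c2)c1,0.043,7.367,train,7.048,7.51
28,Cc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)O)c2)c1,0.061,7.215,train,7.334,6.942
29,CC(C)(C)c1ccc(Sc2ccc(Br)cc2C(=O)Nc2cccc(C(=O)O)c2)cc1,0.048,7.319,train,7.16,7.241
30,COc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)O)c2)c1,0.008,8.097,train,7.888,8.175
31,Cc1ccc(NC(=O)c2cc(Cl)ccc2Sc2ccc(C(C)(C)C)cc2)cc1C(=O)O,0.11,6.959,train,7.178,7.027
32,COc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2ccc(C)c(C(=O)O)c2)c1,0.087,7.06,test,7.861,6.858
33,CCc1ccc(Sc2ccccc2C(=O)NCCCC(=O)O)cc1,5.8,5.237,train,5.058,5.253
34,CC(C)(C)c1ccc(Sc2ccccc2C(=O)NCCCC(=O)O)cc1,2.5,5.602,train,5.748,5.885
35,O=C(O)CCCNC(=O)c1ccccc1Sc1ccc2ccccc2c1,8.6,5.066,train,4.598,4.817
36,O=C(O)CCCCNC(=O)c1ccccc1Sc1ccc2ccccc2c1,8.3,5.081,train,5.086,4.795
37,COC(=O)CCNC(=O)c1ccccc1Sc1ccc2ccccc2c1,7.1,5.149,test,5.377,4.857
38,O=C(O)CCCCCNC(=O)c1ccccc1Sc1ccc2ccccc2c1,4.4,5.357,train,5.657,5.416
39,O=C(O)c1ccc(NC(=O)c2ccccc2Sc2ccc3ccccc3c2)cc1,1.0,6.0,train,5.882,5.902
40,O=C(O)c1cccc(NC(=O)c2ccccc2Sc2ccc3ccccc3c2)c1,1.5,5.824,train,5.75,5.99
41,O=C(O)c1ccc(CNC(=O)c2ccccc2Sc2ccc3ccccc3c2)cc1,1.3,5.886,test,6.722,5.405
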