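id,structure,pred_mlr,pred_comfa
T30,COc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)O)c2)c1,7.888,8.175
N1,Cc1ccc(Sc2ccc(C(C(F)(F)F)(C(F)(F)F)C(F)(F)F)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2)c1,9.032,8.35
N2,Cc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2)c1,8.274,8.323
N3,COc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2)c1,8.626,8.322
N4,Cc1ccc(Sc2ccc(C(I)(I)I)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2)c1,8.744,8.304
N5,Cc1ccc(Sc2ccc(C(C)(C)C)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2O)c1,8.26,8.36
N6,Cc1ccc(Sc2ccc(C(I)(I)I)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2O)c1,8.828,8.357
N7,Cc1ccc(Sc2ccc(C(C(F)(F)F)(C(F)(F)F)C(F)(F)F)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2C)c1,9.123,8.374
N8,Cc1ccc(Sc2ccc(C(C(F)(F)F)(C(F)(F)F)C(F)(F)F)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2N)c1,8.816,8.378
N9,Cc1ccc(Sc2ccc(C(C(F)(F)F)(C(F)(F)F)C(F)(F)F)cc2)c(C(=O)Nc2cccc(C(=O)N(C)C)c2O)c1,9.024,8.388
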