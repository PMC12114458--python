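disinfectant,exact_num,exact_den,within1_num,within1_den,within2_num,within2_den
Mikrozid,12,14,14,14,14,14
Klinosept,11,14,13,14,14,14
Glutanol,14,14,14,14,14,14
Peroklin,13,14,14,14,14,14
Clor2Klin,14,14,14,14,14,14
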