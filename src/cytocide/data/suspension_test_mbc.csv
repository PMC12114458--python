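strain,Mikrozid,Klinosept,Glutanol,Peroklin,Clor2Klin
Kp16,30,30,1.25,0.07,0.004
Ec2,30,60,2.5,0.15,0.003
Ec17,30,60,2.5,0.15,0.003
Ec10538,30,40,1.25,0.15,0.004
Ab88,15,30,2.5,0.07,0.001
Ab108,15,30,2.5,0.07,0.001
Ps1696,10,20,1.25,0.47,0.003
Ps1707,10,20,1.25,1.87,0.003
Ps15442,30,40,2.5,0.07,0.003
Sa13358,40,40,0.62,0.07,0.006
Sa47,40,60,1.25,0.07,0.003
Sa6538,60,40,2.5,0.07,0.025
Ef16,30,30,5,0.07,0.001
Eh10541,30,40,2.5,0.07,0.003
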