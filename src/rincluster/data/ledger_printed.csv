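state_label,G_value,unit,composition
Res16-E-R1,-1000.000000000000,hartree,model
Res16-E-TS1,-999.975299177717,hartree,model
Res16-E-P1,-999.982789104473,hartree,model
Res16-E-R2,-1076.384382705911,hartree,model+1w
Res16-E-TS2,-1076.361912925641,hartree,model+1w
Res16-E-P2,-1076.394581755112,hartree,model+1w
Res21-E-R1,-1010.000000000000,hartree,model
Res21-E-TS1,-1009.968924771966,hartree,model
Res21-E-P1,-1009.988844789936,hartree,model
Res21-E-R2,-1086.380876782748,hartree,model+1w
Res21-E-TS2,-1086.377848940017,hartree,model+1w
Res21-E-P2,-1086.401434241294,hartree,model+1w
Res16-Q-R1,-1020.000000000000,hartree,model
Res16-Q-TS1,-1019.955060439459,hartree,model
Res16-Q-P1,-1019.980079982029,hartree,model
Res16-Q-R2,-1096.346773711983,hartree,model+1w
Res16-Q-TS2,-1096.344383309827,hartree,model+1w
Res20-Q-R1,-1030.000000000000,hartree,model
Res20-Q-TS1,-1029.944861390258,hartree,model
Res20-Q-P1,-1029.962709726359,hartree,model
Res20-Q-R2,-1106.354901079315,hartree,model+1w
Res20-Q-TS2,-1106.352191956871,hartree,model+1w
Res21-Q-R1,-1040.000000000000,hartree,model
Res21-Q-TS1,-1039.951554516296,hartree,model
Res21-Q-P1,-1039.970677733548,hartree,model
Res21-Q-R2,-1116.360478684347,hartree,model+1w
Res21-Q-TS2,-1116.359363163340,hartree,model+1w
Res23-Q-R1,-1050.000000000000,hartree,model
Res23-Q-TS1,-1049.949960914858,hartree,model
Res23-Q-P1,-1049.970996453835,hartree,model
Res23-Q-R2,-1126.352670037302,hartree,model+1w
Res23-Q-TS2,-1126.350598355433,hartree,model+1w
water,-76.400000000000,hartree,model
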