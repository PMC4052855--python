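symbol,Z,mass_g_mol,e_k_ev,tau_auger_fs
H,1,1.0079,13.6,
C,6,12.0107,284.0,10.0
N,7,14.0067,409.9,7.1
O,8,15.9994,543.1,5.0
Mg,12,24.3050,1303.0,
P,15,30.9738,2145.5,
S,16,32.0650,2472.0,1.3
Ca,20,40.0780,4038.5,
Mn,25,54.9380,6539.0,0.62
Fe,26,55.8450,7112.0,0.55
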