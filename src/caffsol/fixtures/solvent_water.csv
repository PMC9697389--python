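temperature_K,rho0_g_cm3,eta0_mPa_s,v1bar_cm3_mol
293.15,0.99821,1.0016,18.047
298.15,0.99705,0.89,18.068
303.15,0.99565,0.7972,18.094
308.15,0.99403,0.719,18.123
313.15,0.99222,0.6527,18.156
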