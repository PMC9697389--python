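temperature_K,rho0_g_cm3,eta0_mPa_s,v1bar_cm3_mol
293.15,1.004763,1.047049,18.18
298.15,1.003607,0.925919,18.21
303.15,1.002211,0.825809,18.23
308.15,1.000595,0.741721,18.26
313.15,0.99879,0.670657,18.3
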