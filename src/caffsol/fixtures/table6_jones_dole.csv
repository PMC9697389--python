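temperature_K,B_ss_dm3_mol,B_water_dm3_mol
293.15,0.501,0.414
298.15,0.49,0.421
303.15,0.461,0.429
308.15,0.449,0.432
313.15,0.436,0.435
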