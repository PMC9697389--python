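temperature_K,vphi0_cm3_mol,sv_cm3_kg_mol2,sigma_cm3_mol,r2
293.15,131.46,75.46,0.503,0.9497
298.15,132.47,73.66,0.234,0.9882
303.15,133.62,72.56,0.304,0.9796
308.15,134.15,74.28,0.375,0.9706
313.15,134.33,82.78,0.237,0.9903
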