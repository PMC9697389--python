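temperature_K,v2bar_cm3_mol,v1bar_cm3_mol,dmu1_kJ_mol,dmu2_kJ_mol
293.15,131.46,18.18,9.42,91.77
298.15,132.47,18.21,9.28,91.62
303.15,133.62,18.23,9.15,88.78
308.15,134.15,18.26,9.03,88.31
313.15,134.33,18.3,8.92,87.43
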