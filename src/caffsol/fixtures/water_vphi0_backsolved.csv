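temperature_K,vphi0_cm3_mol
293.15,142.93
298.15,143.53
303.15,144.45
308.15,145.2
313.15,145.91
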