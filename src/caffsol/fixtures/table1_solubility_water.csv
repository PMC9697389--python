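temperature_K,solubility_g_per_kg
293.15,16.33
298.15,20.71
303.15,25.29
308.15,34.83
313.15,43.9
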