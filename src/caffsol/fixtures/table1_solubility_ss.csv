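temperature_K,solubility_g_per_kg
293.15,43.83
298.15,49.26
303.15,55.73
308.15,68.62
313.15,89.22
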