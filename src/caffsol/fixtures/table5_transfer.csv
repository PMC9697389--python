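temperature_K,transfer_volume_cm3_mol,specific_volume_cm3_g
293.15,-11.47,0.68
298.15,-11.06,0.68
303.15,-10.83,0.69
308.15,-11.05,0.69
313.15,-11.58,0.69
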