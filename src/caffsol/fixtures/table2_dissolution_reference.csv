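system,dsol_G_kJ_mol,dsol_H_kJ_mol
water,13.3,0.41
ss,13.28,0.13
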