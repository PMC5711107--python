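# Built-in material registry.
# Z and A are effective values for compounds; I is the mean excitation energy.
name,Z,A_g_mol,density_g_cm3,I_eV
nickel,28,58.6934,8.902,311.0
tantalum,73,180.94788,16.654,718.0
aluminum,13,26.9815385,2.6989,166.0
air,7.36,14.6,1.205e-3,85.7
water,10,18.0153,0.998,75.0
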