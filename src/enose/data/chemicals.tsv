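name	molecular_weight_g_per_mol	density_kg_per_L
ethanol	46.07	0.789
acetone	58.08	0.791
ethyl acetate	88.106	0.897
acetonitrile	41.05	0.786
methyl propyl disulfide	122.25	0.982
2-nonanone	142.24	0.821
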