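name	molecular_weight_da	brain_conc_ng_ml	skin_conc_ng_ml
s100b_monomer	10700	10.0	0.288
s100b_dimer	21000	10.0	0.288
gfap	26000	1.0	0.0
uchl1	26000	7.6	0.0
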