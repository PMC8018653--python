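# Letrozole input parameter set, female rat.
# Identical to the male set except absorption rate and oral clearance.
name: letrozole_female
molecular_weight: 285.0      # g/mol
logp: 2.5
blood_plasma_ratio: 0.8
fu_plasma: 0.4
intrinsic_solubility: 62.0   # ug/mL
fa: 0.99
ka: 0.49                     # 1/h
cl_systemic_ml_min: 0.21     # oral clearance, mL/min (0.051 L/h/kg at 250 g)
fu_brain: 0.58
psb_ml_min: 0.84
psc_ml_min: 0.42
pse_ml_min: 80.0
cl_b_in: 0.0
cl_b_out: 0.0
cl_c_in: 0.0
cl_c_out: 0.0
cl_met_brain: 0.0
kp_scalar: 1.0
ionization: neutral
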