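# Letrozole input parameter set, male rat.
# Units are embedded in the key names; clearance is the in-vivo oral
# (dose/AUC) clearance at the 250 g reference body weight.
name: letrozole_male
molecular_weight: 285.0      # g/mol
logp: 2.5
blood_plasma_ratio: 0.8
fu_plasma: 0.4
intrinsic_solubility: 62.0   # ug/mL
fa: 0.99
ka: 0.29                     # 1/h
cl_systemic_ml_min: 0.77     # oral clearance, mL/min (0.185 L/h/kg at 250 g)
fu_brain: 0.58
psb_ml_min: 0.84             # BBB passive PS (Crone-Renkin, 0.469 mL/min/g x 1.8 g)
psc_ml_min: 0.42             # BCSFB passive PS, half of PSB
pse_ml_min: 80.0             # CSFBB passive PS, high-permeability assumption
cl_b_in: 0.0                 # L/h; letrozole is not a transporter substrate
cl_b_out: 0.0
cl_c_in: 0.0
cl_c_out: 0.0
cl_met_brain: 0.0            # L/h; brain metabolism assumed negligible
kp_scalar: 1.0
ionization: neutral          # assumption flag: treated as essentially neutral at pH 7.4
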