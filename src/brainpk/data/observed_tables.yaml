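# Observed group-mean PK values from the single-dose and steady-state rat
# letrozole studies (plasma and brain ECF), used as fixture constants for
# the derived-metric arithmetic and for predicted/observed evaluation.
# Units: concentrations ng/mL, AUC h.ng/mL, times h, CL mL/h/kg.
fu_plasma: 0.38
single_dose:
  male:
    n_ecf: 3
    n_plasma: 4
    tmax_ecf: 4.7
    tmax_plasma: 6.5
    t_half_plasma: 9.23
    cmax_ecf: 260.0
    cmax_plasma: 1060.0
    auc12_ecf: 2410.0
    auc12_plasma: 10700.0
    auc72_plasma: 24860.0
    cl_ml_h_kg: 146.0
  female:
    n_ecf: 4
    n_plasma: 4
    tmax_ecf: 6.9
    tmax_plasma: 8.5
    t_half_plasma: 34.0
    cmax_ecf: 660.0
    cmax_plasma: 1200.0
    auc12_ecf: 5750.0
    auc12_plasma: 11700.0
    auc72_plasma: 54390.0
    cl_ml_h_kg: 57.4
steady_state:
  male:
    n_ecf: 6
    n_plasma: 6
    tmax_ecf: 3.3
    tmax_plasma: 3.3
    cmax_ecf: 490.0
    cmax_plasma: 1490.0
    auc12_ecf: 4820.0
    auc12_plasma: 14800.0
    auc24_plasma: 24800.0
    cl_ml_h_kg: 200.6
  female:
    n_ecf: 6
    n_plasma: 4
    tmax_ecf: 6.5
    tmax_plasma: 5.3
    cmax_ecf: 2290.0
    cmax_plasma: 4830.0
    auc12_ecf: 23990.0
    auc12_plasma: 49300.0
    auc24_plasma: 102970.0
    cl_ml_h_kg: 39.3
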