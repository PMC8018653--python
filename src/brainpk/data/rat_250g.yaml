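# Default rat physiology, 250 g body weight.
# Volumes in L, flows in L/h; compiled from standard published rat
# physiology tables (organ weights as fraction of body weight, regional
# blood flows as fraction of cardiac output 0.235 L/min/kg^0.75).
name: rat_250g
body_weight_kg: 0.25
volumes:
  lung: 0.00125
  adipose: 0.0175
  bone: 0.0125
  gut: 0.00675
  heart: 0.000825
  kidney: 0.001825
  liver: 0.00915
  muscle: 0.101
  skin: 0.0475
  spleen: 0.0005
  rest: 0.0309
flows:
  cardiac_output: 4.985103
  adipose: 0.348957
  bone: 0.608183
  gut: 0.653048
  heart: 0.24427
  kidney: 0.702899
  liver: 0.104687
  muscle: 1.385859
  skin: 0.289136
  spleen: 0.099702
  rest: 0.44866
v_arterial: 0.006167   # 1/3 of 7.4% BW blood volume
v_venous: 0.012333     # 2/3 of 7.4% BW blood volume
brain_weight_g: 1.8
v_brain_blood: 7.2e-05 # ~4% of brain volume, additional to systemic blood
v_brain_mass: 0.0018
v_csf: 0.00025
q_brain: 0.099702
q_bulk: 0.000132       # brain mass -> CSF bulk flow (~2.2 uL/min CSF turnover)
q_sink: 0.000132       # CSF -> brain blood sink flow
hematocrit: 0.45
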