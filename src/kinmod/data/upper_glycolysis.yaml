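# Mass-action toy model of the upper part of glycolysis: constant glucose
# influx, hexokinase (GLC + ATP -> G6P + ADP), phosphoglucoisomerase
# (G6P <-> F6P), phosphofructokinase (F6P + ATP -> FBP + ADP), FBP
# consumption by the lower pathway, and ATP regeneration (ADP -> ATP).
provenance: >
  Toy upper-glycolysis network in the style of introductory systems-biology
  textbooks; rate constants are documented fixture choices (no published
  parameter table exists for this toy model).
parameters:
  v0: 1.0     # constant glucose influx [mM min^-1]
  k_hk: 0.5   # hexokinase mass-action constant [mM^-1 min^-1]
  kf_pgi: 2.0 # phosphoglucoisomerase forward constant [min^-1]
  kr_pgi: 1.0 # phosphoglucoisomerase reverse constant [min^-1]
  k_pfk: 0.6  # phosphofructokinase mass-action constant [mM^-1 min^-1]
  k_fbp: 0.8  # FBP consumption by the lower pathway [min^-1]
  k_reg: 0.4  # ATP regeneration from ADP [min^-1]
initial_state:
  GLC: 1.0
  G6P: 0.0
  F6P: 0.0
  FBP: 0.0
  ATP: 8.0    # adenylate pool ATP + ADP = 10 mM, conserved
  ADP: 2.0
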