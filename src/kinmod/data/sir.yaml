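# Compartmental epidemic models.  Fractions of a closed population; rates in
# day^-1.  The vital-dynamics variant keeps the total population constant
# (birth rate == death rate) and, with these parameters, spirals into the
# endemic equilibrium with damped oscillations.
provenance: >
  Classic Kermack-McKendrick structure; the vital-dynamics parameters are
  documented placeholders producing damped oscillations toward the endemic
  equilibrium (PLACEHOLDER, original parameterisation not reproduced).
parameters:
  beta: 1.0       # transmission rate [day^-1]
  gamma: 0.1      # recovery rate [day^-1]
  sigma: 0.2      # incubation rate E -> I, SEIR only [day^-1]
  mu_d: 0.02      # disease-induced death rate, SIRD only [day^-1]
  mu: 0.01        # birth = background death rate, vital dynamics [day^-1]
  N_total: 1.0    # constant total population (fractions)
initial_state:
  S: 0.99
  I: 0.01
  R: 0.0
  E: 0.0
  D: 0.0
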