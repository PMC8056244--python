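# Four-compartment model of HIV infection of CD4+ T cells:
# uninfected (T), latently infected (L), actively infected (A) cells and
# free virus (V).  Parameter values are the published values of the cited
# original model (units: day^-1, mm^-3 where applicable).
provenance: >
  Perelson, Kirschner & de Boer (1993), Dynamics of HIV infection of
  CD4+ T cells; published parameter set.
parameters:
  s: 10.0          # supply of new T cells from the thymus [mm^-3 day^-1]
  r: 0.03          # T-cell logistic growth rate [day^-1]
  T_max: 1500.0    # T-cell carrying capacity [mm^-3]
  mu_T: 0.02       # death rate of uninfected and latently infected cells [day^-1]
  mu_b: 0.24       # death rate of actively infected cells [day^-1]
  mu_V: 2.4        # clearance rate of free virus [day^-1]
  k1: 2.4e-5       # infection rate constant [mm^3 day^-1]
  k2: 3.0e-3       # latent -> active activation rate [day^-1]
  N_burst: 1000.0  # virions produced per actively infected cell (varied)
initial_state:
  T: 1000.0
  L: 0.0
  A: 0.0
  V: 1.0e-3
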