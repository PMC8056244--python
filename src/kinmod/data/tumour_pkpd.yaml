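# Transit-compartment PK-PD model of tumour growth under anticancer
# treatment: proliferating mass x1 with saturating growth, drug-induced kill
# k2*c(t)*x1, and a cascade of three damaged compartments x2 -> x3 -> x4;
# total tumour weight w = x1 + x2 + x3 + x4.  The pharmacokinetic part is a
# single dose at t_dose with first-order elimination,
# c(t) = dose * exp(-k_el * (t - t_dose)) for t >= t_dose.
provenance: >
  Transit-compartment tumour growth structure after Simeoni et al. (2004).
  Parameter values are documented placeholders chosen to give the
  qualitative dynamics (exponential-then-linear growth, dose-dependent
  regrowth delay); the parameter tables of the original are not reproduced
  here.  PLACEHOLDER values, flagged.
parameters:
  lambda0: 0.3    # first-order growth rate of small tumours [day^-1]
  lambda1: 0.7    # linear growth rate of large tumours [g day^-1]
  psi: 20.0       # sharpness of the exponential-to-linear switch [-]
  k1: 0.8         # transit rate through damaged compartments [day^-1]
  k2: 0.5         # drug potency [ml ug^-1 day^-1] (scanned in analyses)
  dose: 1.0       # drug exposure scale at administration [ug ml^-1]
  k_el: 1.0       # first-order drug elimination rate [day^-1]
  t_dose: 9.0     # administration day [day]
initial_state:
  x1: 0.05        # initial proliferating tumour mass [g]
  x2: 0.0
  x3: 0.0
  x4: 0.0
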