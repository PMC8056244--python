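# kinmod

Construct, simulate and analyse kinetic models of biochemical reaction
networks — ordinary differential equation (ODE) models of the form

```
dx/dt = N · v(x, t)
```

where `x` are compound concentrations, `N` is the stoichiometric matrix and
`v` the vector of reaction rates.  The package targets the everyday workflow
of computational systems biology: assemble a model programmatically from
named parameters, compounds and rate laws; integrate it; find steady states;
quantify control with metabolic control analysis; follow isotope-labelling
experiments; and exchange models through a supported subset of SBML Level 3.

## What the package does

- **Model construction** (`kinmod.core`): a mutable `Model` holds
  parameters, derived parameters (computed from other parameters, with cycle
  detection), compounds, reactions and optional metadata (human-readable
  names, database identifiers, units).  Rates may be catalog rate laws or
  arbitrary Python callables; stoichiometries, argument names and modifiers
  are validated at assembly time.
- **Rate-law catalog** (`kinmod.ratelaws`): constant, (reversible) mass
  action, (reversible) Michaelis–Menten and Hill kinetics, available both as
  plain functions and as declarative objects that carry enough structure for
  symbolic differentiation and SBML export.
- **Simulation** (`kinmod.simulate`): `Simulator` wraps `scipy`'s LSODA/BDF
  integrators in an experiment-like session — successive `simulate()` calls
  continue from the previous end point, and model edits between calls take
  effect immediately.  Steady states are found by integrating over expanding
  time horizons; `parameter_scan` warm-starts each steady state from the
  previous one; `phase_plane_field` evaluates the exact right-hand side on a
  grid.
- **Metabolic control analysis** (`kinmod.mca`): scaled elasticities,
  parameter elasticities and response coefficients by central finite
  differences with multiplicative displacement, plus ready-to-plot heat-map
  data with a symmetric colour range.
- **Isotope labelling** (`kinmod.labelled`): expand a kinetic model into its
  `2^N` isotopomer variants per labelled compound from a declarative atom
  map.  Variant rates partition the base rate by isotopomer fractions, so
  total concentrations of the expanded model track the base model exactly,
  for any kinetics.
- **Linear label models** (`kinmod.linlabel`): label dynamics at metabolic
  steady state reduce to the linear system `dy/dt = A·y + b`; the package
  builds `A` from an atom map, stationary fluxes and pool sizes, solves it
  numerically or in closed form via the matrix exponential, and locates
  label-front arrival times (time of maximal labelling rate).
- **SBML subset I/O** (`kinmod.sbml_io`): catalog-built models export to
  SBML Level 3 Version 2 and import back losslessly; foreign documents
  within the subset are compiled from their MathML.  Custom Python rates
  cannot be serialised and fail with an error naming the reaction.
- **Fixtures** (`kinmod.fixtures`): ready-made example models — an upper
  glycolysis pathway, a four-compartment HIV CD4+ T-cell infection model, a
  transit-compartment tumour-growth PK-PD model, the SIR/SEIR/SIRD epidemic
  family (with a vital-dynamics variant) and a seeded random linear pathway
  for label experiments.

## Worked example

A two-step pathway — constant influx into `S`, Michaelis–Menten conversion
to `P`, first-order efflux:

```python
from kinmod import Model, Simulator, steady_state, elasticities
from kinmod.ratelaws import Constant, MassAction, MichaelisMenten

m = Model(parameters={"v0": 1.0, "vmax": 3.0, "km": 0.5, "k_out": 2.0},
          compounds=["S", "P"])
m.add_reaction("influx", Constant("v0"), {"S": 1})
m.add_reaction("conversion", MichaelisMenten("vmax", "km", "S"),
               {"S": -1, "P": 1})
m.add_reaction("efflux", MassAction("k_out", ("P",)), {"P": -1})

tc = Simulator(m, {"S": 0.0, "P": 0.0}).simulate(5.0, n_points=50)
print(tc.to_frame().tail(3).round(6))
#     time     S         P
# 48   4.8  0.25  0.499913
# 49   4.9  0.25  0.499928
# 50   5.0  0.25  0.499941

ss = steady_state(m, {"S": 0.0, "P": 0.0})
print(ss)                      # {'S': 0.25, 'P': 0.5}
print(m.get_fluxes(ss))        # every flux -> 1.0 (stationary throughput)

print(elasticities(m, ss).values.round(4))
#                  S    P
# influx      0.0000  0.0
# conversion  0.6667  0.0
# efflux      0.0000  1.0
```

The numbers have closed forms: at stationarity the conversion flux equals
the influx `v0 = 1`, giving `S* = km·v0/(vmax−v0) = 0.25` and
`P* = v0/k_out = 0.5`; the scaled elasticity of a Michaelis–Menten rate is
`km/(km+S) = 0.5/0.75 = 2/3`.

### Command line

```bash
kinmod fixtures                                   # list bundled models
kinmod simulate fixture:sir --t-end 100           # time course as TSV
kinmod steady-state fixture:upper_glycolysis
kinmod scan fixture:sir --parameter beta --values 0.5,1,2
kinmod convert fixture:upper_glycolysis --out glycolysis.xml
kinmod simulate glycolysis.xml --t-end 50         # SBML files work as sources
```

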