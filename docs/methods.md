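# Methods

## Model representation

A model is the tuple (parameters, derived parameters, compounds, reactions).
Each reaction has a rate function, an ordered argument list naming
parameters and compounds, a stoichiometry mapping compounds to signed
coefficients, and optional modifiers (compounds or the reserved token
`time` that influence the rate without appearing in the stoichiometry).
The right-hand side is assembled exactly as `dx/dt = N · v(x, t)` with `N`
the compounds-by-reactions stoichiometric matrix; no simplification or
symbolic processing happens on the numeric path, so the assembly identity
`RHS = N @ v` holds to machine precision.

Assumptions baked into the representation:

- deterministic, well-stirred, single-compartment kinetics (no spatial
  structure, no stochasticity);
- concentrations are real numbers; small negative excursions from the
  integrator (≲ 1e-9) are tolerated silently, larger ones are logged;
- derived parameters form a directed acyclic graph over parameters; cycles
  are rejected at definition or update time.

The `Model` is mutable and the `Simulator` holds a live view: edits between
simulation segments (e.g. a treatment protocol changing a parameter) take
effect at the next call.  This mirrors the structure of a wet-lab
experiment — one model object, a session that advances in time.

## Rate-law catalog

| law | expression | parameters |
| --- | --- | --- |
| constant | `v = k` | `k` |
| mass_action | `v = k·∏Sᵢ` | `k` |
| reversible_mass_action | `v = kf·∏Sᵢ − kr·∏Pⱼ` | `kf, kr` |
| michaelis_menten | `v = vmax·S/(km+S)` | `vmax, km` |
| reversible_michaelis_menten | `v = (vf·S/kms − vr·P/kmp)/(1 + S/kms + P/kmp)` | `vf, vr, kms, kmp` |
| hill | `v = vmax·Sⁿ/(kdⁿ+Sⁿ)` | `vmax, kd, n` |

Catalog laws validate parameter domains (positive Michaelis and
dissociation constants, positive Hill coefficient) and carry a descriptor
used for symbolic differentiation (via `sympy`) and SBML export.  A plain
Python callable is always accepted as a rate but is opaque: it can be
integrated and differentiated numerically, not exported.

## Numerical choices

- **Integration**: `scipy.integrate.solve_ivp`, LSODA by default (automatic
  stiff/non-stiff switching), BDF selectable; `rtol = 1e-8`,
  `atol = 1e-10`.  Output grids are uniform (`n_points + 1` points).
- **Steady states**: integrate over expanding horizons
  `t ∈ {10¹, …, 10⁶}` until `max|dx/dt| < tol·(1 + max|x|)` with
  `tol = 1e-8`; optionally polish with a Newton solve.  The steady-state
  search never advances the simulation session.
- **Parameter scans** warm-start each steady state from the previous
  solution (numerical continuation); non-convergent rows are returned as
  NaN rather than failing the whole scan, and the scanned parameter is
  restored afterwards.
- **Elasticities and response coefficients**: central differences with
  multiplicative displacement `x·(1±δ)`, `δ = 1e-4` (additive `δ` when the
  base value is zero).  Scaled coefficients divide by the local rate and are
  NaN where the rate is zero.  Central differencing makes the error
  `O(δ²)`; the test suite verifies the quadratic shrinkage and checks all
  catalog laws against exact symbolic derivatives.
- **Heat-map data** use a symmetric colour range `[−m, +m]` with `m` the
  largest finite magnitude, so positive and negative control are visually
  comparable; NaN cells are masked.

## Isotope labelling

`expand_label_model` turns each labelled compound with `N` traced atoms
into `2^N` isotopomer species named `base__b₁…b_N` (leftmost bit = atom 0)
and each mapped reaction into one variant per substrate isotopomer
combination.  A variant's rate is the base rate evaluated at the *total*
concentrations, multiplied by the probability of drawing that isotopomer
combination (product of isotopomer fractions).  Summing over variants
recovers the base rate exactly, so totals of the expanded model follow the
base model for arbitrary kinetics — not just mass action.

Design constraints (enforced with errors):

- mapped reactions must be irreversible with ±1 stoichiometric
  coefficients, and a compound may not appear on both sides — otherwise the
  atom bookkeeping is ambiguous;
- every reaction touching a labelled compound must carry an atom map; an
  empty map means the compound is consumed without label transfer (efflux);
- influx reactions declare the label pattern of the entering material as
  `influx_patterns: {reaction: (compound, pattern)}`.

## Linear label models

At metabolic steady state the label fraction `yᵢ` of each atom position
obeys the linear compartmental system `dy/dt = A·y + b`, where a reaction
with stationary flux `v` producing pool `p` of size `X_p` contributes
`−v/X_p` on the diagonal and `+v/X_p` for each sourced position; influxes
with a labelled medium feed `b`.  Construction verifies flux balance per
pool (tolerance 1e-8) and the resulting `A` has the compartmental sign
structure (non-positive diagonal, non-negative off-diagonal).

Solutions: numerically (same integrator settings) or in closed form,
`y(t) = y_ss + expm(A·t)·(y₀ − y_ss)` via `scipy.linalg.expm`.  The time of
maximal labelling rate — the label "wave front" — is located as the argmax
of the first difference quotient (`numpy.gradient`); ties resolve to the
earliest time, curves that are constant are reported as degenerate with a
warning, and fewer than three samples are rejected.  `to_model()` rebuilds
the linear system as an ordinary kinetic model from catalog laws, which
makes every linear label model SBML-exportable.

## SBML subset

Export targets SBML Level 3 Version 2 with a single unit-size compartment.
Catalog rate laws serialise to canonical content MathML plus a private
annotation (`urn:kinmod:ratelaw`) recording the law kind and argument
roles; import uses the annotation to rebuild first-class catalog laws, and
falls back to compiling the MathML into a generic (non-re-exportable) rate
for foreign documents.  Derived parameters are written as assignment rules
obtained by symbolically tracing the Python function.  Out of scope —
rejected with an error listing the constructs: events, delays, algebraic
and rate rules, assignment rules targeting species, function definitions,
initial assignments and multiple compartments.  A structural validator
checks well-formedness, required attributes, id uniqueness and symbol
resolution without external tooling.

The asymmetry is deliberate: *import* accepts anything in the structural
subset, *export* requires catalog laws, because only those carry enough
declarative structure to guarantee a faithful round trip (verified to
1e-9 over random states in the test suite).

## Fixture models and parameter provenance

- **Upper glycolysis** — glucose influx, hexokinase,
  phosphoglucoisomerase (reversible), phosphofructokinase, FBP consumption
  and ATP regeneration over six compounds; mass-action kinetics with
  illustrative rate constants chosen so the pathway has a unique positive
  steady state (unit flux through every glycolytic step, conserved
  adenylate pool ATP+ADP = 10).  Annotated with ChEBI identifiers;
  SBML-exportable.
- **HIV CD4+ T-cell model** — uninfected (T), latently (L) and actively (A)
  infected T cells and free virus (V), with logistic T-cell proliferation
  and burst-size-proportional virion production.  Parameters are the
  published values of the classic four-compartment model (supply
  `s = 10 mm⁻³ day⁻¹`, growth `r = 0.03 day⁻¹`, carrying capacity
  `T_max = 1500 mm⁻³`, death rates `μ_T = 0.02`, `μ_b = 0.24`,
  `μ_V = 2.4 day⁻¹`, infection `k₁ = 2.4e-5 mm³ day⁻¹`, activation
  `k₂ = 3e-3 day⁻¹`, burst size `N = 1000`).  With these values the
  untreated infection settles at a persistently lowered T-cell count; the
  two-segment treatment protocol reduces `N` after year 3.  Custom logistic
  rate → not SBML-exportable.
- **Tumour PK-PD** — proliferating mass `x1` with a saturating growth law
  (smooth exponential-to-linear switch, exponent `ψ = 20`) and three
  first-order transit compartments toward death; a single drug dose at
  day 9 enters as an analytic exponentially eliminated concentration.
  Parameter values are illustrative (documented in the data file), chosen
  to show the qualitative dose-response behaviour: the day-18 tumour weight
  decreases monotonically with drug potency `k₂`.
- **Epidemic family** — SIR, SEIR, SIRD and SIR with vital dynamics, all
  mass action, normalised population.  Rates are illustrative
  (`β = 1.0`, `γ = 0.1`, `σ = 0.2`, `μ_d = 0.02`, `μ = 0.01`); the
  vital-dynamics variant keeps births equal to background deaths and its
  endemic equilibrium is a stable focus (complex eigenvalues with negative
  real part), i.e. damped epidemic waves.
- **Random linear pathway** — `n` pools in a chain with fully labelled
  influx, identity atom transitions, equal stationary flux everywhere and
  pool sizes drawn uniformly from [1, 10] with a caller-supplied seed.  It
  emulates the canonical label-propagation experiment (a label wave moving
  down a pathway); it does not attempt realistic pool-size correlations,
  measurement noise or bidirectional exchange fluxes.

Fixture parameters live in YAML data files inside the package; files whose
values are illustrative rather than published are flagged as such in the
file comments.

## Limitations

- No stochastic simulation, spatial transport, events/delays or
  differential-algebraic constraints.
- Isotopomer expansion is exponential in the number of traced atoms per
  compound (`2^N` species); it is intended for small motifs, with the
  linear label models covering the stationary large-network case.
- Elasticities are finite-difference approximations (error `O(δ²)`), not
  exact derivatives; symbolic exactness is only used as a test oracle.
- The SBML layer covers the subset described above, not the full standard,
  and its validator is structural, not schema-complete.
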