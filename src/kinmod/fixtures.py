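"""Replicated example models and synthetic generators.

Four families of fixture models exercise the whole toolkit and serve as the
CLI-addressable registry (``fixture:NAME``):

* a mass-action toy model of upper glycolysis (elasticity heat maps),
* a four-compartment model of HIV infection of CD4+ T cells,
* a transit-compartment PK-PD model of tumour growth under a single dose,
* the classic SIR family (SIR, SEIR, SIRD, and SIR with vital dynamics),
* a seeded random linear pathway for label-propagation studies.

Parameter values live in YAML data files next to the package
(``kinmod/data/``), so editing a parameterisation never requires touching
code; each file documents its provenance, and placeholder values are flagged
there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .core import Model
from .labelled import LabelMapping
from .ratelaws import Constant, MassAction, ReversibleMassAction
from .simulate import Simulator, TimeCourse


def _load_data(name: str) -> dict:
    path = resources.files("kinmod").joinpath("data", f"{name}.yaml")
    return yaml.safe_load(path.read_text())


@dataclass
class FixtureEntry:
    """A registered fixture: builder, default initial state, provenance."""

    name: str
    builder: Callable[[], Model]
    initial_state: dict[str, float]
    note: str
    sbml_exportable: bool


# ---------------------------------------------------------------------------
# upper glycolysis
# ---------------------------------------------------------------------------

def upper_glycolysis() -> Model:
    """Mass-action toy model of the upper part of glycolysis.

    Constant glucose influx, hexokinase, a reversible phosphoglucoisomerase,
    phosphofructokinase, FBP consumption by the lower pathway, and ATP
    regeneration from ADP.  Entirely catalog-built, hence SBML-exportable.
    """
    data = _load_data("upper_glycolysis")
    m = Model(parameters=data["parameters"],
              compounds=["GLC", "G6P", "F6P", "FBP", "ATP", "ADP"])
    m.add_reaction("influx", Constant("v0"), {"GLC": 1})
    m.add_reaction(
        "hexokinase", MassAction("k_hk", ("GLC", "ATP")),
        {"GLC": -1, "ATP": -1, "G6P": 1, "ADP": 1},
    )
    m.add_reaction(
        "phosphoglucoisomerase",
        ReversibleMassAction("kf_pgi", "kr_pgi", ("G6P",), ("F6P",)),
        {"G6P": -1, "F6P": 1},
    )
    m.add_reaction(
        "phosphofructokinase", MassAction("k_pfk", ("F6P", "ATP")),
        {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1},
    )
    m.add_reaction("fbp_consumption", MassAction("k_fbp", ("FBP",)), {"FBP": -1})
    m.add_reaction(
        "atp_regeneration", MassAction("k_reg", ("ADP",)),
        {"ADP": -1, "ATP": 1},
    )
    m.annotate("GLC", common_name="glucose",
               identifiers=["https://identifiers.org/CHEBI:17234"], unit="mM")
    m.annotate("ATP", common_name="ATP",
               identifiers=["https://identifiers.org/CHEBI:15422"], unit="mM")
    return m


# ---------------------------------------------------------------------------
# HIV / CD4+ T-cell model
# ---------------------------------------------------------------------------

def _logistic_growth(r, t_max, t, l, a):
    """Logistic proliferation of uninfected T cells, capped by T+L+A."""
    return r * t * (1.0 - (t + l + a) / t_max)


def hiv_t4cell() -> Model:
    """Four-compartment model of HIV infection dynamics.

    States: uninfected (T), latently infected (L) and actively infected (A)
    CD4+ T cells, and free infectious virus (V).  Virion production is
    proportional to the burst size ``N_burst``; the antiretroviral protocol
    reduces ``N_burst`` mid-simulation.  The logistic growth term is a custom
    rate, so this fixture is not SBML-exportable.
    """
    data = _load_data("hiv_t4cell")
    m = Model(parameters=data["parameters"], compounds=["T", "L", "A", "V"])
    m.add_derived_parameter(
        "p_burst", lambda n, mu: n * mu, ("N_burst", "mu_b")
    )
    m.add_reaction("t_supply", Constant("s"), {"T": 1})
    m.add_reaction(
        "t_growth", _logistic_growth, {"T": 1},
        args=("r", "T_max", "T", "L", "A"), modifiers=("L", "A"),
    )
    m.add_reaction("t_death", MassAction("mu_T", ("T",)), {"T": -1})
    m.add_reaction(
        "infection", MassAction("k1", ("V", "T")),
        {"T": -1, "L": 1, "V": -1},
    )
    m.add_reaction("l_death", MassAction("mu_T", ("L",)), {"L": -1})
    m.add_reaction(
        "activation", MassAction("k2", ("L",)), {"L": -1, "A": 1}
    )
    m.add_reaction("a_death", MassAction("mu_b", ("A",)), {"A": -1})
    m.add_reaction(
        "v_production", MassAction("p_burst", ("A",)), {"V": 1},
        modifiers=("A",),
    )
    m.add_reaction("v_clearance", MassAction("mu_V", ("V",)), {"V": -1})
    m.annotate("T", common_name="uninfected CD4+ T cells", unit="mm^-3")
    m.annotate("V", common_name="free infectious HIV", unit="mm^-3")
    return m


def hiv_total_t_cells(tc: TimeCourse) -> pd.Series:
    """The overall T-cell population T + L + A along a time course."""
    frame = tc.to_frame()
    return frame["T"] + frame["L"] + frame["A"]


def run_hiv_treatment(
    reduction: float, years: float = 10.0, switch_year: float = 3.0,
    n_points: int = 200,
) -> TimeCourse:
    """Two-segment protocol: reduce the burst size N after ``switch_year``.

    ``reduction`` is the fractional decrease of N (0.25 or 0.75 in the
    classic azidothymidine experiment).  Time unit: days.
    """
    if years <= switch_year:
        raise ValueError("the protocol needs years > switch_year")
    model = hiv_t4cell()
    data = _load_data("hiv_t4cell")
    sim = Simulator(model, data["initial_state"])
    sim.simulate(switch_year * 365.0, n_points=n_points)
    model.update_parameter(
        "N_burst", model.parameters["N_burst"] * (1.0 - reduction)
    )
    sim.simulate(years * 365.0, n_points=n_points)
    return sim.get_full_results()


# ---------------------------------------------------------------------------
# tumour growth PK-PD
# ---------------------------------------------------------------------------

def _saturating_growth(lambda0, lambda1, psi, x1, x2, x3, x4):
    """Exponential growth switching smoothly to linear at large tumour mass."""
    w = x1 + x2 + x3 + x4
    return lambda0 * x1 / (1.0 + (lambda0 / lambda1 * w) ** psi) ** (1.0 / psi)


def _drug_kill(k2, dose, k_el, t_dose, x1, t):
    """Second-order kill by the drug concentration c(t) of a single dose."""
    if t < t_dose:
        return 0.0
    return k2 * dose * math.exp(-k_el * (t - t_dose)) * x1


def tumour_growth_pkpd() -> Model:
    """Transit-compartment PK-PD model of tumour growth under treatment.

    Proliferating mass ``x1`` grows with a saturating law and is pushed by
    the drug-kill term through three first-order transit compartments
    ``x2 -> x3 -> x4`` toward cell death; total tumour weight is
    w = x1 + x2 + x3 + x4.  The pharmacokinetics reduce to a single dose at
    ``t_dose`` with first-order elimination.  Custom rate functions make
    this fixture non-exportable to SBML.
    """
    data = _load_data("tumour_pkpd")
    m = Model(parameters=data["parameters"], compounds=["x1", "x2", "x3", "x4"])
    m.add_reaction(
        "growth", _saturating_growth, {"x1": 1},
        args=("lambda0", "lambda1", "psi", "x1", "x2", "x3", "x4"),
        modifiers=("x2", "x3", "x4"),
    )
    m.add_reaction(
        "drug_kill", _drug_kill, {"x1": -1, "x2": 1},
        args=("k2", "dose", "k_el", "t_dose", "x1", "time"),
        modifiers=("time",),
    )
    m.add_reaction("transit_1", MassAction("k1", ("x2",)), {"x2": -1, "x3": 1})
    m.add_reaction("transit_2", MassAction("k1", ("x3",)), {"x3": -1, "x4": 1})
    m.add_reaction("transit_3", MassAction("k1", ("x4",)), {"x4": -1})
    return m


def tumour_weight(tc: TimeCourse) -> pd.Series:
    """Total tumour weight w = x1 + x2 + x3 + x4 along a time course."""
    frame = tc.to_frame()
    return frame[["x1", "x2", "x3", "x4"]].sum(axis=1)


def run_tumour_protocol(k2: float, t_end: float = 18.0,
                        n_points: int = 180) -> TimeCourse:
    """Simulate 18 days of tumour growth with a single dose at day 9.

    Integrated in two segments split at the administration time so the
    discontinuous drug input never crosses an integrator step.
    """
    model = tumour_growth_pkpd()
    data = _load_data("tumour_pkpd")
    model.update_parameter("k2", k2)
    t_dose = model.parameters["t_dose"]
    sim = Simulator(model, data["initial_state"])
    sim.simulate(t_dose, n_points=n_points // 2)
    sim.simulate(t_end, n_points=n_points // 2)
    return sim.get_full_results()


# ---------------------------------------------------------------------------
# SIR family
# ---------------------------------------------------------------------------

SIR_VARIANTS = ("SIR", "SEIR", "SIRD", "SIR_vital")


def sir(variant: str = "SIR") -> Model:
    """Compartmental epidemic models: SIR, SEIR, SIRD, SIR with vital dynamics.

    All variants are catalog-built (mass action throughout).  The
    vital-dynamics variant keeps the total population constant (birth rate
    equal to the background death rate) and spirals into the endemic
    equilibrium with damped oscillations under the fixture parameters.
    """
    if variant not in SIR_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {SIR_VARIANTS}")
    data = _load_data("sir")
    p = data["parameters"]

    if variant == "SEIR":
        compounds = ["S", "E", "I", "R"]
    elif variant == "SIRD":
        compounds = ["S", "I", "R", "D"]
    else:
        compounds = ["S", "I", "R"]

    keep = {"beta", "gamma"}
    if variant == "SEIR":
        keep.add("sigma")
    if variant == "SIRD":
        keep.add("mu_d")
    if variant == "SIR_vital":
        keep.update({"mu", "N_total"})
    m = Model(parameters={k: p[k] for k in keep}, compounds=compounds)

    infection_target = "E" if variant == "SEIR" else "I"
    m.add_reaction(
        "infection", MassAction("beta", ("S", "I")),
        {"S": -1, infection_target: 1},
        modifiers=("I",) if variant == "SEIR" else (),
    )
    if variant == "SEIR":
        m.add_reaction(
            "incubation", MassAction("sigma", ("E",)), {"E": -1, "I": 1}
        )
    m.add_reaction("recovery", MassAction("gamma", ("I",)), {"I": -1, "R": 1})
    if variant == "SIRD":
        m.add_reaction(
            "disease_death", MassAction("mu_d", ("I",)), {"I": -1, "D": 1}
        )
    if variant == "SIR_vital":
        m.add_derived_parameter(
            "birth_flux", lambda mu, n: mu * n, ("mu", "N_total")
        )
        m.add_reaction("birth", Constant("birth_flux"), {"S": 1})
        for compartment in ("S", "I", "R"):
            m.add_reaction(
                f"death_{compartment}", MassAction("mu", (compartment,)),
                {compartment: -1},
            )
    return m


def sir_initial_state(variant: str = "SIR") -> dict[str, float]:
    data = _load_data("sir")
    y0 = data["initial_state"]
    return {c: y0[c] for c in sir(variant).compounds}


# ---------------------------------------------------------------------------
# random linear pathway (label propagation)
# ---------------------------------------------------------------------------

#: documented range pool sizes are drawn from
POOL_SIZE_RANGE = (1.0, 10.0)


def random_linear_pathway(
    n_pools: int = 5, seed: int = 2015, flux: float = 1.0
) -> tuple[LabelMapping, dict[str, float], dict[str, float]]:
    """A linear non-reversible pathway of randomly sized metabolite pools.

    Fully labelled influx -> M1 -> ... -> Mn -> efflux, one labellable atom
    per pool, identity atom transitions, and the same stationary flux through
    every step.  Pool sizes are drawn uniformly from ``POOL_SIZE_RANGE`` with
    the given seed.  Returns ``(mapping, steady_fluxes, pool_sizes)`` ready
    for :func:`kinmod.linlabel.build_linear_label_model`.
    """
    if n_pools < 2:
        raise ValueError(f"need at least 2 pools, got {n_pools}")
    rng = np.random.default_rng(seed)
    pools = [f"M{i + 1}" for i in range(n_pools)]
    sizes = rng.uniform(*POOL_SIZE_RANGE, size=n_pools)
    mapping = LabelMapping(
        labelled_compounds={p: 1 for p in pools},
        transitions={
            f"step_{i + 1}": [(pools[i], {0: (pools[i + 1], 0)})]
            for i in range(n_pools - 1)
        } | {"efflux": [(pools[-1], {})]},
        influx_patterns={"influx": (pools[0], "1")},
    )
    fluxes = {f"step_{i + 1}": flux for i in range(n_pools - 1)}
    fluxes["influx"] = flux
    fluxes["efflux"] = flux
    pool_sizes = dict(zip(pools, sizes))
    return mapping, fluxes, pool_sizes


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _entries() -> dict[str, FixtureEntry]:
    reg = {
        "upper_glycolysis": FixtureEntry(
            "upper_glycolysis", upper_glycolysis,
            _load_data("upper_glycolysis")["initial_state"],
            "mass-action toy model of upper glycolysis", True,
        ),
        "hiv_t4cell": FixtureEntry(
            "hiv_t4cell", hiv_t4cell,
            _load_data("hiv_t4cell")["initial_state"],
            "four-compartment HIV / CD4+ T-cell model", False,
        ),
        "tumour_pkpd": FixtureEntry(
            "tumour_pkpd", tumour_growth_pkpd,
            _load_data("tumour_pkpd")["initial_state"],
            "transit-compartment PK-PD tumour growth model", False,
        ),
    }
    for variant in SIR_VARIANTS:
        key = variant.lower()
        reg[key] = FixtureEntry(
            key, lambda v=variant: sir(v), sir_initial_state(variant),
            f"compartmental epidemic model ({variant})", True,
        )
    return reg


def registry() -> dict[str, FixtureEntry]:
    """All registered fixtures, keyed by CLI-addressable name."""
    return _entries()


def get_fixture(name: str) -> tuple[Model, dict[str, float]]:
    """Build a registered fixture and return (model, default initial state)."""
    reg = _entries()
    if name not in reg:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(reg)}"
        )
    entry = reg[name]
    return entry.builder(), dict(entry.initial_state)
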