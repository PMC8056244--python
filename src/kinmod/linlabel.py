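"""Linear label models: isotope tracing at metabolic steady state.

When metabolite concentrations and fluxes are stationary, the label fraction
y_{i,a} of atom position a of compound i obeys a *linear* ODE system

    dy_{i,a}/dt = (1/X_i) * sum_k v_k * (y_src(k) - y_{i,a})

summed over the reactions k that produce position (i, a); X_i is the pool
size, v_k the steady-state flux, and y_src the label fraction of the source
atom (an upstream position, or the external medium fraction y_ext for an
influx, or 0 for an unsourced atom).  In matrix form dy/dt = A y + b with
A having non-positive diagonal and non-negative off-diagonal entries
(compartmental structure), which admits the closed-form solution via the
matrix exponential used here as an exact solver.

This is dramatically cheaper than the full 2**N isotopomer expansion and is
the standard stationary linearisation of label-propagation dynamics.
Reversible exchange fluxes must be supplied as two opposing irreversible
fluxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .core import Model
from .errors import StationarityError
from .labelled import LabelMapping
from .ratelaws import Constant, MassAction

logger = logging.getLogger(__name__)

FLUX_BALANCE_TOL = 1e-8


@dataclass
class LinearLabelModel:
    """dy/dt = A y + b over per-atom-position label fractions."""

    positions: list[tuple[str, int]]       # (compound, atom index), ordered
    A: np.ndarray
    b: np.ndarray
    pool_sizes: dict[str, float]
    fluxes: dict[str, float]
    y_ext: dict[str, float]

    @property
    def position_names(self) -> list[str]:
        return [f"{c}.{a}" for c, a in self.positions]

    def steady_state(self) -> np.ndarray:
        """y_ss with A y_ss + b = 0 (error if A is singular with b != 0)."""
        if np.all(self.b == 0):
            return np.zeros(len(self.positions))
        try:
            return np.linalg.solve(self.A, -self.b)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular system matrix with a nonzero offset; no unique "
                "stationary label distribution"
            ) from exc

    def solve(self, y0: Sequence[float], times: Sequence[float]) -> pd.DataFrame:
        """Exact solution y(t) = y_ss + expm(A t) (y0 - y_ss)."""
        return solve_closed_form(self, y0, times)

    def to_model(self) -> Model:
        """Rebuild the linear system as an ordinary kinetic model.

        Every term is expressed with catalog rate laws (mass action for the
        A-matrix couplings, constant rates for the offset), so the result is
        simulatable, analysable and SBML-exportable like any other model.
        """
        m = Model()
        names = self.position_names
        m.add_compounds(names)
        n = len(names)
        for i in range(n):
            for j in range(n):
                a = self.A[i, j]
                if a == 0:
                    continue
                if i == j:
                    pname = f"k_out_{i}"
                    m.add_parameter(pname, -a)
                    m.add_reaction(
                        f"drain_{i}",
                        MassAction(pname, substrates=(names[i],)),
                        stoichiometry={names[i]: -1.0},
                    )
                else:
                    pname = f"k_{i}_{j}"
                    m.add_parameter(pname, a)
                    m.add_reaction(
                        f"feed_{i}_{j}",
                        MassAction(pname, substrates=(names[j],)),
                        stoichiometry={names[i]: 1.0},
                        modifiers=(names[j],),
                    )
            if self.b[i] != 0:
                pname = f"b_{i}"
                m.add_parameter(pname, self.b[i])
                m.add_reaction(
                    f"influx_{i}",
                    Constant(pname),
                    stoichiometry={names[i]: 1.0},
                )
        return m


def build_linear_label_model(
    mapping: LabelMapping,
    steady_fluxes: Mapping[str, float],
    pool_sizes: Mapping[str, float],
    y_ext: Mapping[str, float] | None = None,
) -> LinearLabelModel:
    """Assemble the linear label system from an atom transition map.

    Parameters
    ----------
    mapping
        Labelled compounds with atom counts, transitions and influx patterns.
    steady_fluxes
        reaction -> stationary flux, all >= 0 (reversible exchanges must be
        split beforehand).
    pool_sizes
        compound -> stationary concentration, all > 0.
    y_ext
        reaction -> external label fraction for influx reactions (default 1
        for every influx: fully labelled medium).

    Raises
    ------
    StationarityError
        If inflow and outflow do not balance at some pool (tolerance 1e-8).
    """
    y_ext = dict(y_ext) if y_ext is not None else {}
    for rxn in mapping.influx_patterns:
        y_ext.setdefault(rxn, 1.0)

    for compound in mapping.labelled_compounds:
        if compound not in pool_sizes or pool_sizes[compound] <= 0:
            raise ValueError(f"pool size for {compound!r} must be positive")
    for rxn, v in steady_fluxes.items():
        if v < 0:
            raise ValueError(
                f"flux {rxn!r} is negative; split reversible exchanges into "
                f"two irreversible fluxes"
            )

    # flux balance per labelled compound
    production: dict[str, float] = dict.fromkeys(mapping.labelled_compounds, 0.0)
    consumption: dict[str, float] = dict.fromkeys(mapping.labelled_compounds, 0.0)
    for rxn, entries in mapping.transitions.items():
        v = steady_fluxes[rxn]
        produced = {p for _, amap in entries for p, _ in amap.values()}
        for substrate, _ in entries:
            consumption[substrate] += v
        for p in produced:
            production[p] += v
    for rxn, (compound, _) in mapping.influx_patterns.items():
        production[compound] += steady_fluxes[rxn]
    for compound in mapping.labelled_compounds:
        imbalance = production[compound] - consumption[compound]
        if abs(imbalance) > FLUX_BALANCE_TOL:
            raise StationarityError(
                f"fluxes at pool {compound!r} do not balance "
                f"(in {production[compound]:g}, out {consumption[compound]:g})"
            )

    positions = [
        (compound, a)
        for compound, n in mapping.labelled_compounds.items()
        for a in range(n)
    ]
    index = {pos: i for i, pos in enumerate(positions)}
    A = np.zeros((len(positions), len(positions)))
    b = np.zeros(len(positions))

    for rxn, entries in mapping.transitions.items():
        v = steady_fluxes[rxn]
        produced = {p for _, amap in entries for p, _ in amap.values()}
        sourced: dict[tuple[str, int], tuple[str, int]] = {}
        for substrate, amap in entries:
            for j, (p, m) in amap.items():
                sourced[(p, m)] = (substrate, j)
        for p in produced:
            rate = v / pool_sizes[p]
            for m in range(mapping.labelled_compounds[p]):
                i = index[(p, m)]
                A[i, i] -= rate
                src = sourced.get((p, m))
                if src is not None:
                    A[i, index[src]] += rate
                # unsourced atoms receive unlabelled material: dilution only

    for rxn, (compound, pattern) in mapping.influx_patterns.items():
        v = steady_fluxes[rxn]
        rate = v / pool_sizes[compound]
        for m in range(mapping.labelled_compounds[compound]):
            i = index[(compound, m)]
            A[i, i] -= rate
            if pattern[m] == "1":
                b[i] += rate * y_ext[rxn]

    return LinearLabelModel(
        positions=positions,
        A=A,
        b=b,
        pool_sizes={c: float(pool_sizes[c]) for c in mapping.labelled_compounds},
        fluxes={r: float(v) for r, v in steady_fluxes.items()},
        y_ext=y_ext,
    )


def solve_closed_form(
    llm: LinearLabelModel, y0: Sequence[float], times: Sequence[float]
) -> pd.DataFrame:
    """Exact label curves via the matrix exponential.

    y(t) = y_ss + expm(A t) (y0 - y_ss), one column per atom position named
    ``compound.atomIndex`` plus the leading time column.
    """
    y0 = np.asarray(y0, dtype=float)
    times = np.asarray(times, dtype=float)
    if y0.shape != (len(llm.positions),):
        raise ValueError(
            f"y0 must have one entry per position ({len(llm.positions)})"
        )
    y_ss = llm.steady_state()
    dev0 = y0 - y_ss
    rows = [y_ss + scipy.linalg.expm(llm.A * t) @ dev0 for t in times]
    df = pd.DataFrame(np.vstack(rows), columns=llm.position_names)
    df.insert(0, "time", times)
    return df


def time_of_max_rate(times: Sequence[float], values: Sequence[float]) -> float:
    """Time at which a labelling curve's first derivative is maximal.

    The derivative is a centred finite difference on the given grid (one-sided
    at the ends); ties resolve to the earliest time.  A constant curve is
    degenerate (every point ties); it returns the first time and logs a
    warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points to locate the maximum rate")
    dydt = np.gradient(y, t)
    if np.allclose(dydt, dydt[0]):
        logger.warning("curve has constant slope; time of max rate is degenerate")
    return float(t[int(np.argmax(dydt))])


def curves_to_tsv(curves: pd.DataFrame, path) -> None:
    """Write label curves as TSV: time plus one column per position."""
    curves.to_csv(path, sep="\t", index=False)
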