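"""Metabolic control analysis: elasticities and steady-state responses.

Elasticities are local, scaled sensitivities of one rate to one concentration
or parameter, eps = (x/v) * dv/dx; response coefficients are the systemic
analogue, the scaled sensitivity of a steady-state concentration or flux to a
parameter.  All derivatives are central finite differences with relative
perturbation x*(1 +/- delta) (additive delta when the base value is zero),
which is second-order accurate in delta.

Scaled elasticities are undefined where the rate is zero; such entries are
NaN, never silently zero, and callers are expected to mask them (the
heat-map preparation below does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Model
from .errors import IntegrationError, NonConvergenceError, UnknownSymbolError
from .simulate import steady_state

logger = logging.getLogger(__name__)

DEFAULT_DISPLACEMENT = 1e-4


@dataclass
class ElasticityMatrix:
    """Reactions x (compounds or parameters) sensitivity matrix."""

    values: pd.DataFrame       # rows = reactions, cols = perturbed quantities
    scaled: bool
    displacement: float

    @property
    def reactions(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ResponseTable:
    """Scaled steady-state responses of concentrations and fluxes."""

    concentration_responses: pd.DataFrame   # compounds x parameters
    flux_responses: pd.DataFrame            # reactions x parameters
    base_state: dict[str, float]


def _perturbed_pair(value: float, displacement: float) -> tuple[float, float, float]:
    """(lo, hi, step) for a central difference around ``value``."""
    if value != 0.0:
        lo, hi = value * (1 - displacement), value * (1 + displacement)
    else:
        lo, hi = -displacement, displacement
    return lo, hi, hi - lo


def _flux_vector(model: Model, state: Mapping[str, float], t: float) -> np.ndarray:
    return np.array(list(model.get_fluxes(state, t).values()))


def elasticities(
    model: Model,
    state: Mapping[str, float],
    t: float = 0.0,
    displacement: float = DEFAULT_DISPLACEMENT,
    scaled: bool = True,
) -> ElasticityMatrix:
    """Elasticities of every rate with respect to every compound.

    Scaled entries are (x_i/v_k) * dv_k/dx_i, dimensionless; where v_k = 0
    the scaled entry is NaN.
    """
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    reactions = list(model.reactions)
    compounds = model.compounds
    base_v = _flux_vector(model, state, t)
    out = np.zeros((len(reactions), len(compounds)))
    for j, compound in enumerate(compounds):
        x = float(state[compound])
        lo, hi, step = _perturbed_pair(x, displacement)
        s_lo = dict(state); s_lo[compound] = lo
        s_hi = dict(state); s_hi[compound] = hi
        dv = (_flux_vector(model, s_hi, t) - _flux_vector(model, s_lo, t)) / step
        out[:, j] = dv
        if scaled:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, j] = np.where(base_v != 0, x * dv / base_v, np.nan)
    return ElasticityMatrix(
        values=pd.DataFrame(out, index=reactions, columns=compounds),
        scaled=scaled,
        displacement=displacement,
    )


def parameter_elasticities(
    model: Model,
    state: Mapping[str, float],
    t: float = 0.0,
    displacement: float = DEFAULT_DISPLACEMENT,
    scaled: bool = True,
    parameters: Sequence[str] | None = None,
) -> ElasticityMatrix:
    """Elasticities of every rate with respect to model parameters.

    Derived parameters are refreshed at each perturbed evaluation, so
    sensitivities propagate through them automatically.
    """
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    names = list(parameters) if parameters is not None else list(model.parameters)
    unknown = [p for p in names if p not in model.parameters]
    if unknown:
        raise UnknownSymbolError(f"unknown parameters {unknown}")
    reactions = list(model.reactions)
    base_v = _flux_vector(model, state, t)
    out = np.zeros((len(reactions), len(names)))
    for j, pname in enumerate(names):
        p = model.parameters[pname]
        lo, hi, step = _perturbed_pair(p, displacement)
        try:
            model.update_parameter(pname, hi)
            v_hi = _flux_vector(model, state, t)
            model.update_parameter(pname, lo)
            v_lo = _flux_vector(model, state, t)
        finally:
            model.update_parameter(pname, p)
        dv = (v_hi - v_lo) / step
        out[:, j] = dv
        if scaled:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, j] = np.where(base_v != 0, p * dv / base_v, np.nan)
    return ElasticityMatrix(
        values=pd.DataFrame(out, index=reactions, columns=names),
        scaled=scaled,
        displacement=displacement,
    )


def response_coefficients(
    model: Model,
    y0: Mapping[str, float],
    parameters: Sequence[str] | None = None,
    displacement: float = DEFAULT_DISPLACEMENT,
    tol: float = 1e-8,
) -> ResponseTable:
    """Scaled responses of steady-state concentrations and fluxes to parameters.

    For each parameter p the steady state is re-solved at p*(1 +/- delta)
    (warm-started from the base solution) and the scaled response
    (p/S) * dS/dp taken by central difference.  Parameters whose perturbation
    destroys the steady state yield NaN columns and a log entry.
    """
    names = list(parameters) if parameters is not None else list(model.parameters)
    unknown = [p for p in names if p not in model.parameters]
    if unknown:
        raise UnknownSymbolError(f"unknown parameters {unknown}")
    base = steady_state(model, y0, tol=tol)
    base_conc = np.array([base[c] for c in model.compounds])
    base_flux = _flux_vector(model, base, 0.0)
    conc = np.zeros((len(model.compounds), len(names)))
    flux = np.zeros((len(model.reactions), len(names)))
    for j, pname in enumerate(names):
        p = model.parameters[pname]
        lo, hi, step = _perturbed_pair(p, displacement)
        try:
            model.update_parameter(pname, hi)
            ss_hi = steady_state(model, base, tol=tol)
            v_hi = _flux_vector(model, ss_hi, 0.0)
            model.update_parameter(pname, lo)
            ss_lo = steady_state(model, base, tol=tol)
            v_lo = _flux_vector(model, ss_lo, 0.0)
        except (NonConvergenceError, IntegrationError) as exc:
            logger.warning("steady state lost perturbing %r: %s", pname, exc)
            conc[:, j] = np.nan
            flux[:, j] = np.nan
            continue
        finally:
            model.update_parameter(pname, p)
        dC = (np.array([ss_hi[c] for c in model.compounds])
              - np.array([ss_lo[c] for c in model.compounds])) / step
        dJ = (v_hi - v_lo) / step
        with np.errstate(divide="ignore", invalid="ignore"):
            conc[:, j] = np.where(base_conc != 0, p * dC / base_conc, np.nan)
            flux[:, j] = np.where(base_flux != 0, p * dJ / base_flux, np.nan)
    return ResponseTable(
        concentration_responses=pd.DataFrame(
            conc, index=model.compounds, columns=names
        ),
        flux_responses=pd.DataFrame(
            flux, index=list(model.reactions), columns=names
        ),
        base_state=base,
    )


def mca_heatmap_data(matrix: pd.DataFrame) -> dict:
    """Prepare a sensitivity matrix for heat-map rendering.

    Returns row/column labels, the value grid, a NaN mask, and a colour range
    symmetric about zero so sign is directly readable: [-m, +m] with m the
    largest finite magnitude ([-1, 1] when the matrix is all zero).
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    values = matrix.to_numpy(dtype=float)
    mask = np.isnan(values)
    if mask.all():
        raise ValueError("matrix contains no finite entries")
    m = float(np.nanmax(np.abs(values)))
    if m == 0.0:
        m = 1.0
    return {
        "row_labels": list(matrix.index),
        "col_labels": list(matrix.columns),
        "values": values,
        "mask": mask,
        "vmin": -m,
        "vmax": m,
    }
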