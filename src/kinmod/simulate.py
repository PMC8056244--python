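"""Numerical integration, steady states, parameter scans and phase planes.

A :class:`Simulator` is a session on a model, in the way an experiment is
performed on a biological entity: it holds the current time and state and
accumulates time-course segments.  Successive :meth:`Simulator.simulate`
calls continue where the previous one ended, so protocols such as "change a
parameter at day 9 and keep integrating" are two calls with a parameter
update in between.

The default backend is scipy's LSODA (variable-order, variable-step,
stiffness-switching); BDF is the stiff fallback.  Steady states are found by
integrating over expanding horizons rather than Newton iteration, which is
robust for stiff biological systems; an optional Newton polish with a
finite-difference Jacobian can be switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .core import Model
from .errors import IntegrationError, NonConvergenceError, UnknownSymbolError

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: expanding integration horizons tried by the steady-state search
STEADY_STATE_WINDOWS = (1e1, 1e2, 1e3, 1e4, 1e5, 1e6)


@dataclass
class TimeCourse:
    """One simulation segment: time grid, states and the derived fluxes."""

    times: np.ndarray
    states: np.ndarray          # rows = times, cols = compounds (model order)
    fluxes: np.ndarray          # rows = times, cols = reactions
    compounds: list[str]
    reactions: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != len(self.times):
            raise ValueError("states row count must match times")
        if self.fluxes.shape[0] != len(self.times):
            raise ValueError("fluxes row count must match times")

    def to_frame(self) -> pd.DataFrame:
        """States as a labelled table, one row per time point."""
        df = pd.DataFrame(self.states, columns=self.compounds)
        df.insert(0, "time", self.times)
        return df

    def fluxes_to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fluxes, columns=self.reactions)
        df.insert(0, "time", self.times)
        return df

    def get_variables(self, names: Sequence[str]) -> pd.DataFrame:
        """Column subset of the state table, keeping the time column."""
        unknown = [n for n in names if n not in self.compounds]
        if unknown:
            raise UnknownSymbolError(f"unknown compounds {unknown}")
        return self.to_frame()[["time", *names]]

    def get_fluxes(self, names: Sequence[str]) -> pd.DataFrame:
        unknown = [n for n in names if n not in self.reactions]
        if unknown:
            raise UnknownSymbolError(f"unknown reactions {unknown}")
        return self.fluxes_to_frame()[["time", *names]]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.compounds, self.states[-1]))

    @staticmethod
    def concat(segments: Sequence["TimeCourse"]) -> "TimeCourse":
        """Join contiguous segments, dropping duplicated junction points."""
        if not segments:
            raise ValueError("no segments to concatenate")
        times = [segments[0].times]
        states = [segments[0].states]
        fluxes = [segments[0].fluxes]
        for seg in segments[1:]:
            skip = 1 if np.isclose(seg.times[0], times[-1][-1]) else 0
            times.append(seg.times[skip:])
            states.append(seg.states[skip:])
            fluxes.append(seg.fluxes[skip:])
        return TimeCourse(
            times=np.concatenate(times),
            states=np.vstack(states),
            fluxes=np.vstack(fluxes),
            compounds=segments[0].compounds,
            reactions=segments[0].reactions,
        )


class Simulator:
    """An integration session bound to a model.

    Parameters
    ----------
    model
        The model to integrate; read live, so mutations between ``simulate``
        calls take effect.
    y0
        Initial concentrations keyed by compound.
    t0
        Session start time (default 0).
    method
        Any ``scipy.integrate.solve_ivp`` method name; "LSODA" by default.
    """

    def __init__(
        self,
        model: Model,
        y0: Mapping[str, float],
        t0: float = 0.0,
        method: str = "LSODA",
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
    ) -> None:
        self.model = model
        self.method = method
        self.rtol = rtol
        self.atol = atol
        self.current_time = float(t0)
        self.current_state = {c: float(y0[c]) for c in model.compounds}
        self.segments: list[TimeCourse] = []

    # -- state management --------------------------------------------------

    def set_state(self, updates: Mapping[str, float]) -> "Simulator":
        """Override concentrations mid-protocol (e.g. an instantaneous dose)."""
        for name, value in updates.items():
            if name not in self.current_state:
                raise UnknownSymbolError(f"unknown compound {name!r}")
            self.current_state[name] = float(value)
        return self

    # -- integration -------------------------------------------------------

    def _integrate(self, t_span, t_eval=None, method=None):
        y0 = np.array([self.current_state[c] for c in self.model.compounds])
        sol = solve_ivp(
            self.model._rhs_array,
            t_span,
            y0,
            method=method or self.method,
            t_eval=t_eval,
            rtol=self.rtol,
            atol=self.atol,
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration over t={t_span} failed: {sol.message}"
            )
        return sol

    def simulate(self, t_end: float, n_points: int = 100) -> TimeCourse:
        """Integrate from the current time to ``t_end``.

        The session advances: a subsequent call continues from ``t_end`` with
        the final state, so multi-segment protocols concatenate seamlessly.
        """
        if t_end <= self.current_time:
            raise ValueError(
                f"t_end={t_end} must exceed the current time "
                f"{self.current_time}"
            )
        t_eval = np.linspace(self.current_time, t_end, n_points + 1)
        sol = self._integrate((self.current_time, t_end), t_eval=t_eval)
        states = sol.y.T
        fluxes = np.array([
            list(self.model.get_fluxes(
                dict(zip(self.model.compounds, row)), t
            ).values())
            for t, row in zip(sol.t, states)
        ])
        tc = TimeCourse(
            times=sol.t,
            states=states,
            fluxes=fluxes,
            compounds=self.model.compounds,
            reactions=list(self.model.reactions),
        )
        self.segments.append(tc)
        self.current_time = float(sol.t[-1])
        self.current_state = tc.final_state()
        return tc

    def get_full_results(self) -> TimeCourse:
        """All accumulated segments joined into one time course."""
        return TimeCourse.concat(self.segments)

    # -- steady states -----------------------------------------------------

    def simulate_to_steady_state(
        self, tol: float = 1e-8, newton_polish: bool = False
    ) -> dict[str, float]:
        """Integrate over expanding horizons until d|x|/dt is negligible.

        Convergence: max|dx/dt| < tol * (1 + max|x|).  The session itself is
        not advanced; the converged state is returned.
        """
        state = dict(self.current_state)
        t = self.current_time
        for window in STEADY_STATE_WINDOWS:
            saved_time, saved_state = self.current_time, dict(self.current_state)
            self.current_time, self.current_state = t, dict(state)
            try:
                sol = self._integrate((t, t + window))
            finally:
                self.current_time, self.current_state = saved_time, saved_state
            state = dict(zip(self.model.compounds, sol.y[:, -1]))
            t = t + window
            rhs = self.model.get_right_hand_side(state, t)
            resid = max(abs(v) for v in rhs.values())
            scale = 1.0 + max(abs(v) for v in state.values())
            if resid < tol * scale:
                if newton_polish:
                    state = self._newton_polish(state, t)
                return state
        raise NonConvergenceError(
            f"no steady state found by t={t:g} (residual {resid:.3g}, "
            f"tolerance {tol * scale:.3g})"
        )

    def _newton_polish(self, state: dict[str, float], t: float) -> dict[str, float]:
        compounds = self.model.compounds
        x0 = np.array([state[c] for c in compounds])
        root = fsolve(lambda y: self.model._rhs_array(t, y), x0, full_output=False)
        return dict(zip(compounds, root))


def steady_state(
    model: Model,
    y0: Mapping[str, float],
    tol: float = 1e-8,
    **simulator_kwargs,
) -> dict[str, float]:
    """Convenience wrapper: steady state from ``y0`` without keeping a session."""
    return Simulator(model, y0, **simulator_kwargs).simulate_to_steady_state(tol=tol)


def parameter_scan(
    model: Model,
    parameter: str,
    values: Sequence[float],
    y0: Mapping[str, float],
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Steady-state concentrations and fluxes across a parameter sweep.

    Each steady state is warm-started from the previous value's solution
    (continuation), making the scan order-dependent near fold points — the
    scan follows ``values`` exactly as given.  Rows that fail to converge are
    filled with NaN and logged.  The model's parameter is restored afterwards.
    """
    if parameter not in model.parameters:
        raise UnknownSymbolError(f"unknown parameter {parameter!r}")
    values = list(values)
    if not values:
        raise ValueError("parameter_scan needs at least one value")
    original = model.parameters[parameter]
    start = dict(y0)
    rows = []
    try:
        for value in values:
            model.update_parameter(parameter, value)
            row: dict[str, float] = {parameter: value}
            try:
                ss = steady_state(model, start, tol=tol)
            except (NonConvergenceError, IntegrationError) as exc:
                logger.warning("scan %s=%s did not converge: %s", parameter, value, exc)
                row.update(dict.fromkeys(model.compounds, np.nan))
                row.update(dict.fromkeys(model.reactions, np.nan))
            else:
                start = ss  # warm start the next value
                row.update(ss)
                row.update(model.get_fluxes(ss))
            rows.append(row)
    finally:
        model.update_parameter(parameter, original)
    return pd.DataFrame(rows)


def phase_plane_field(
    model: Model,
    compound_x: str,
    compound_y: str,
    x_values: Sequence[float],
    y_values: Sequence[float],
    frozen_state: Mapping[str, float],
    t: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact (dx/dt, dy/dt) vector field over a grid of two compounds.

    All other compounds are held at ``frozen_state``.  Returns meshgrid
    arrays ``(X, Y, U, V)`` ready for a quiver/streamline plot.
    """
    if compound_x == compound_y:
        raise ValueError("phase plane needs two distinct compounds")
    for c in (compound_x, compound_y):
        if c not in model.compounds:
            raise UnknownSymbolError(f"unknown compound {c!r}")
    X, Y = np.meshgrid(np.asarray(x_values, float), np.asarray(y_values, float))
    U = np.zeros_like(X)
    V = np.zeros_like(Y)
    base = {c: float(frozen_state.get(c, 0.0)) for c in model.compounds}
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            state = dict(base)
            state[compound_x] = X[i, j]
            state[compound_y] = Y[i, j]
            rhs = model.get_right_hand_side(state, t)
            U[i, j] = rhs[compound_x]
            V[i, j] = rhs[compound_y]
    return X, Y, U, V
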