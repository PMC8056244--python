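"""Model representation and automatic assembly of the ODE right-hand side.

A :class:`Model` is a mutable container of parameters, derived parameters,
compounds and reactions.  Following the experiment metaphor, the model is the
biological entity (a cell, a population); simulations are separate session
objects (:mod:`kinmod.simulate`) performed *on* the entity.  Every numeric
entry point re-reads the model, so mutations between calls (parameter updates,
added or removed reactions) take effect immediately.

Given stoichiometries and rate laws the ODE system dx/dt = N @ v(x, t) is
assembled automatically; ``N`` is the stoichiometric matrix (rows = compounds,
columns = reactions, both in declaration order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CycleError,
    EmptyModelError,
    NameCollisionError,
    ReservedNameError,
    UnknownSymbolError,
)
from .ratelaws import RateLaw, RateLawDescriptor

logger = logging.getLogger(__name__)

#: reserved token passed to rate functions as the current time
TIME = "time"


@dataclass
class Annotation:
    """Human-readable metadata for a model component.

    Annotations carry a display name, MIRIAM-style identifier URIs and a unit
    string.  They never influence any numeric result.
    """

    common_name: str = ""
    identifiers: list[str] = field(default_factory=list)
    unit: str = ""


@dataclass
class Reaction:
    """One reaction: a rate callable plus its wiring into the model.

    ``args`` are the names whose values are injected, in order, when the rate
    is evaluated: parameters, derived parameters, compounds, or ``"time"``.
    ``stoichiometry`` maps compounds to net coefficients (negative =
    consumed).  ``modifiers`` lists compounds (or ``"time"``) that the rate
    reads without consuming or producing them.
    """

    name: str
    fn: Callable[..., float]
    args: tuple[str, ...]
    stoichiometry: dict[str, float]
    modifiers: tuple[str, ...] = ()
    reversible: bool = False
    rate_law: RateLaw | None = None

    @property
    def descriptor(self) -> RateLawDescriptor | None:
        """Descriptor of the catalog law, or None for user callables."""
        return self.rate_law.descriptor if self.rate_law is not None else None


@dataclass
class DerivedParameter:
    fn: Callable[..., float]
    args: tuple[str, ...]


class Model:
    """A mutable kinetic model: parameters, compounds and reactions.

    Parameters
    ----------
    parameters
        Initial parameter values, name -> float.
    compounds
        Compound names in declaration order.
    """

    def __init__(
        self,
        parameters: Mapping[str, float] | None = None,
        compounds: Iterable[str] | None = None,
    ) -> None:
        self._parameters: dict[str, float] = {}
        self._derived: dict[str, DerivedParameter] = {}
        self._compounds: list[str] = []
        self._reactions: dict[str, Reaction] = {}
        self.metadata: dict[str, Annotation] = {}
        if parameters:
            for name, value in parameters.items():
                self.add_parameter(name, value)
        if compounds:
            self.add_compounds(compounds)

    # -- naming ------------------------------------------------------------

    def _known_names(self) -> set[str]:
        return (
            set(self._parameters)
            | set(self._derived)
            | set(self._compounds)
            | set(self._reactions)
        )

    def _check_free(self, name: str) -> None:
        if not isinstance(name, str) or not name:
            raise ValueError(f"component names must be non-empty strings, got {name!r}")
        if name == TIME:
            raise ReservedNameError(f"{TIME!r} is a reserved token")
        if name in self._known_names():
            raise NameCollisionError(f"name {name!r} is already in use")

    # -- parameters --------------------------------------------------------

    def add_parameter(self, name: str, value: float) -> "Model":
        self._check_free(name)
        self._parameters[name] = float(value)
        return self

    def add_parameters(self, parameters: Mapping[str, float]) -> "Model":
        for name, value in parameters.items():
            self.add_parameter(name, value)
        return self

    def update_parameter(self, name: str, value: float) -> "Model":
        if name not in self._parameters:
            raise UnknownSymbolError(f"unknown parameter {name!r}")
        self._parameters[name] = float(value)
        return self

    def update_parameters(self, parameters: Mapping[str, float]) -> "Model":
        for name, value in parameters.items():
            self.update_parameter(name, value)
        return self

    def remove_parameter(self, name: str) -> "Model":
        if name not in self._parameters:
            raise UnknownSymbolError(f"unknown parameter {name!r}")
        del self._parameters[name]
        return self

    @property
    def parameters(self) -> dict[str, float]:
        """Plain parameter values (a copy; use update_parameter to mutate)."""
        return dict(self._parameters)

    def add_derived_parameter(
        self, name: str, fn: Callable[..., float], args: Sequence[str]
    ) -> "Model":
        """Register a parameter computed from other parameters.

        The value is recomputed lazily before every numeric operation, so it
        always reflects the current parameter values.  ``args`` must reference
        existing parameters or previously declared derived parameters.
        """
        self._check_free(name)
        args = tuple(args)
        if name in args:
            raise CycleError(f"derived parameter {name!r} depends on itself")
        known = set(self._parameters) | set(self._derived)
        unknown = [a for a in args if a not in known]
        if unknown:
            raise UnknownSymbolError(
                f"derived parameter {name!r}: unknown arguments {unknown}"
            )
        self._derived[name] = DerivedParameter(fn=fn, args=args)
        return self

    def update_derived_parameter(
        self, name: str, fn: Callable[..., float], args: Sequence[str]
    ) -> "Model":
        if name not in self._derived:
            raise UnknownSymbolError(f"unknown derived parameter {name!r}")
        args = tuple(args)
        known = set(self._parameters) | set(self._derived)
        unknown = [a for a in args if a not in known and a != name]
        if unknown:
            raise UnknownSymbolError(
                f"derived parameter {name!r}: unknown arguments {unknown}"
            )
        old = self._derived[name]
        self._derived[name] = DerivedParameter(fn=fn, args=args)
        cycle = self._find_cycle()
        if cycle is not None:
            self._derived[name] = old
            raise CycleError(
                "cyclic derived-parameter dependency: " + " -> ".join(cycle)
            )
        return self

    def _find_cycle(self) -> list[str] | None:
        """DFS cycle detection over derived-parameter dependencies."""
        colour: dict[str, int] = {}
        stack: list[str] = []

        def visit(node: str) -> list[str] | None:
            colour[node] = 1
            stack.append(node)
            for dep in self._derived[node].args:
                if dep not in self._derived:
                    continue
                if colour.get(dep) == 1:
                    return stack[stack.index(dep):] + [dep]
                if colour.get(dep, 0) == 0:
                    found = visit(dep)
                    if found:
                        return found
            colour[node] = 2
            stack.pop()
            return None

        for node in self._derived:
            if colour.get(node, 0) == 0:
                found = visit(node)
                if found:
                    return found
        return None

    @property
    def derived_parameters(self) -> dict[str, DerivedParameter]:
        return dict(self._derived)

    def _resolved_parameters(self) -> dict[str, float]:
        """Parameters plus derived parameters, evaluated in dependency order.

        Declaration order is a valid topological order because registration
        only accepts already-known arguments; ``update_derived_parameter``
        re-checks acyclicity, so iterating by a fresh topological sort keeps
        updates safe too.
        """
        values = dict(self._parameters)
        pending = dict(self._derived)
        while pending:
            progressed = False
            for name in list(pending):
                dp = pending[name]
                if all(a in values for a in dp.args):
                    values[name] = float(dp.fn(*(values[a] for a in dp.args)))
                    del pending[name]
                    progressed = True
            if not progressed:  # pragma: no cover - guarded at registration
                raise CycleError(
                    f"cannot resolve derived parameters {sorted(pending)}"
                )
        return values

    # -- compounds ---------------------------------------------------------

    def add_compound(self, name: str) -> "Model":
        self._check_free(name)
        self._compounds.append(name)
        return self

    def add_compounds(self, names: Iterable[str]) -> "Model":
        for name in names:
            self.add_compound(name)
        return self

    def remove_compound(self, name: str) -> "Model":
        if name not in self._compounds:
            raise UnknownSymbolError(f"unknown compound {name!r}")
        users = [
            r.name
            for r in self._reactions.values()
            if name in r.stoichiometry or name in r.args
        ]
        if users:
            raise ValueError(f"compound {name!r} is used by reactions {users}")
        self._compounds.remove(name)
        return self

    @property
    def compounds(self) -> list[str]:
        """Compound names in declaration order."""
        return list(self._compounds)

    # -- reactions ---------------------------------------------------------

    def add_reaction(
        self,
        name: str,
        rate: Callable[..., float] | RateLaw,
        stoichiometry: Mapping[str, float],
        args: Sequence[str] | None = None,
        modifiers: Sequence[str] = (),
        reversible: bool | None = None,
    ) -> "Model":
        """Register a reaction.

        ``rate`` is either a catalog :class:`~kinmod.ratelaws.RateLaw` (in
        which case ``args`` and ``reversible`` default to the law's own) or an
        arbitrary callable taking values for ``args`` in order.
        """
        self._check_free(name)
        rate_law = rate if isinstance(rate, RateLaw) else None
        if rate_law is not None:
            if args is None:
                args = rate_law.args
            if reversible is None:
                reversible = rate_law.reversible
        if args is None:
            raise ValueError(f"reaction {name!r}: args required for custom rates")
        args = tuple(args)
        modifiers = tuple(modifiers)
        reversible = bool(reversible)

        stoichiometry = {k: float(v) for k, v in stoichiometry.items()}
        bad = [c for c in stoichiometry if c not in self._compounds]
        if bad:
            raise UnknownSymbolError(
                f"reaction {name!r}: stoichiometry references undeclared "
                f"compounds {bad}"
            )
        if not any(v != 0 for v in stoichiometry.values()):
            raise ValueError(
                f"reaction {name!r}: needs at least one nonzero coefficient"
            )
        overlap = set(modifiers) & set(stoichiometry)
        if overlap:
            raise ValueError(
                f"reaction {name!r}: modifiers {sorted(overlap)} also appear "
                f"in the stoichiometry"
            )
        valid = self._known_names() | {TIME}
        unresolved = [a for a in args if a not in valid]
        if unresolved:
            raise UnknownSymbolError(
                f"reaction {name!r}: unresolvable argument names {unresolved}"
            )
        for m in modifiers:
            if m != TIME and m not in self._compounds:
                raise UnknownSymbolError(
                    f"reaction {name!r}: modifier {m!r} is not a compound"
                )
        for a in args:
            if (a in self._compounds and a not in stoichiometry
                    and a not in modifiers):
                raise UnknownSymbolError(
                    f"reaction {name!r}: compound argument {a!r} must appear "
                    f"in the stoichiometry or be declared a modifier"
                )
            if a == TIME and TIME not in modifiers:
                raise UnknownSymbolError(
                    f"reaction {name!r}: declare 'time' as a modifier to use "
                    f"it as a rate argument"
                )

        fn = rate_law if rate_law is not None else rate
        self._reactions[name] = Reaction(
            name=name,
            fn=fn,
            args=args,
            stoichiometry=stoichiometry,
            modifiers=modifiers,
            reversible=reversible,
            rate_law=rate_law,
        )
        return self

    def remove_reaction(self, name: str) -> "Model":
        if name not in self._reactions:
            raise UnknownSymbolError(f"unknown reaction {name!r}")
        del self._reactions[name]
        return self

    @property
    def reactions(self) -> dict[str, Reaction]:
        return dict(self._reactions)

    # -- metadata ----------------------------------------------------------

    def annotate(
        self,
        component: str,
        common_name: str = "",
        identifiers: Iterable[str] = (),
        unit: str = "",
    ) -> "Model":
        """Attach an annotation to a declared component (never numeric)."""
        if component not in self._known_names():
            raise UnknownSymbolError(f"unknown component {component!r}")
        self.metadata[component] = Annotation(
            common_name=common_name, identifiers=list(identifiers), unit=unit
        )
        return self

    def strip_metadata(self) -> "Model":
        self.metadata.clear()
        return self

    # -- numerics ----------------------------------------------------------

    def _namespace(self, concentrations: Mapping[str, float], t: float) -> dict:
        missing = [c for c in self._compounds if c not in concentrations]
        if missing:
            raise UnknownSymbolError(f"state is missing compounds {missing}")
        extra = [c for c in concentrations if c not in self._compounds]
        if extra:
            raise UnknownSymbolError(f"state has unknown compounds {extra}")
        negative = [c for c in self._compounds if concentrations[c] < 0]
        if negative:
            # integrators transiently undershoot by round-off; only report
            # undershoot beyond that scale at warning level
            worst = min(concentrations[c] for c in negative)
            level = logging.WARNING if worst < -1e-9 else logging.DEBUG
            logger.log(
                level,
                "negative concentrations at t=%s for %s; evaluation proceeds",
                t, negative,
            )
        ns = self._resolved_parameters()
        ns.update({c: float(concentrations[c]) for c in self._compounds})
        ns[TIME] = float(t)
        return ns

    def get_fluxes(
        self, concentrations: Mapping[str, float], t: float = 0.0
    ) -> dict[str, float]:
        """Evaluate every reaction rate at the given state, insertion order."""
        ns = self._namespace(concentrations, t)
        return {
            name: float(r.fn(*(ns[a] for a in r.args)))
            for name, r in self._reactions.items()
        }

    def get_stoichiometric_matrix(self) -> np.ndarray:
        """N with rows = compounds and columns = reactions, declaration order."""
        if not self._compounds or not self._reactions:
            raise EmptyModelError(
                "stoichiometric matrix needs at least one compound and one reaction"
            )
        mat = np.zeros((len(self._compounds), len(self._reactions)))
        row = {c: i for i, c in enumerate(self._compounds)}
        for k, r in enumerate(self._reactions.values()):
            for c, coeff in r.stoichiometry.items():
                mat[row[c], k] = coeff
        return mat

    def get_stoichiometric_df(self) -> pd.DataFrame:
        """The stoichiometric matrix as a labelled table."""
        return pd.DataFrame(
            self.get_stoichiometric_matrix(),
            index=self.compounds,
            columns=list(self._reactions),
        )

    def get_right_hand_side(
        self, concentrations: Mapping[str, float], t: float = 0.0
    ) -> dict[str, float]:
        """d[compound]/dt = (N @ v)(x, t), keyed by compound."""
        fluxes = self.get_fluxes(concentrations, t)
        rhs = dict.fromkeys(self._compounds, 0.0)
        for r in self._reactions.values():
            v = fluxes[r.name]
            for c, coeff in r.stoichiometry.items():
                rhs[c] += coeff * v
        return rhs

    def _rhs_array(self, t: float, y: np.ndarray) -> np.ndarray:
        """Vectorised right-hand side for the integrator (compound order)."""
        state = dict(zip(self._compounds, y))
        rhs = self.get_right_hand_side(state, t)
        return np.array([rhs[c] for c in self._compounds])

    def copy(self) -> "Model":
        """Deep-enough copy: containers are fresh, callables shared."""
        m = Model()
        m._parameters = dict(self._parameters)
        m._derived = dict(self._derived)
        m._compounds = list(self._compounds)
        m._reactions = {
            name: Reaction(
                name=r.name,
                fn=r.fn,
                args=r.args,
                stoichiometry=dict(r.stoichiometry),
                modifiers=r.modifiers,
                reversible=r.reversible,
                rate_law=r.rate_law,
            )
            for name, r in self._reactions.items()
        }
        m.metadata = {
            k: Annotation(a.common_name, list(a.identifiers), a.unit)
            for k, a in self.metadata.items()
        }
        return m

    def __repr__(self) -> str:
        return (
            f"Model({len(self._compounds)} compounds, "
            f"{len(self._reactions)} reactions, "
            f"{len(self._parameters)} parameters, "
            f"{len(self._derived)} derived)"
        )
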