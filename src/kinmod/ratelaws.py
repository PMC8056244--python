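"""Catalog of named kinetic rate laws.

Two surfaces are provided:

* plain numeric functions (:func:`mass_action`, :func:`michaelis_menten`, ...)
  for direct evaluation, and
* catalog classes (:class:`MassAction`, :class:`MichaelisMenten`, ...) that bind
  a law to concrete parameter and compound names.  Catalog-built reactions carry
  a :class:`RateLawDescriptor`, which is what makes them serialisable to SBML;
  reactions built from arbitrary user callables carry none and cannot be
  exported.

The reversible Michaelis-Menten form is the one-substrate/one-product
convenience kinetics

    v = (Vf*S/KmS - Vr*P/KmP) / (1 + S/KmS + P/KmP)

Multi-substrate mass action multiplies every listed substrate concentration
once; a stoichiometric exponent above one is expressed by listing the compound
repeatedly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ParameterDomainError

__all__ = [
    "constant",
    "mass_action",
    "reversible_mass_action",
    "michaelis_menten",
    "reversible_michaelis_menten",
    "hill",
    "RateLawDescriptor",
    "RateLaw",
    "Constant",
    "MassAction",
    "ReversibleMassAction",
    "MichaelisMenten",
    "ReversibleMichaelisMenten",
    "Hill",
    "CATALOG_KINDS",
]


# ---------------------------------------------------------------------------
# plain numeric forms
# ---------------------------------------------------------------------------

def constant(k: float) -> float:
    """Zero-order rate, independent of any concentration."""
    return k


def mass_action(k: float, *substrates: float) -> float:
    """v = k * prod(S_i)."""
    v = k
    for s in substrates:
        v *= s
    return v


def reversible_mass_action(
    kf: float, kr: float, substrates: Sequence[float], products: Sequence[float]
) -> float:
    """Net mass action v = kf*prod(S) - kr*prod(P); may be negative."""
    return mass_action(kf, *substrates) - mass_action(kr, *products)


def michaelis_menten(vmax: float, km: float, s: float) -> float:
    """Irreversible Michaelis-Menten, v = vmax*S/(km+S)."""
    if km <= 0:
        raise ParameterDomainError(f"michaelis_menten requires km > 0, got {km}")
    return vmax * s / (km + s)


def reversible_michaelis_menten(
    vmax_f: float, vmax_r: float, km_s: float, km_p: float, s: float, p: float
) -> float:
    """One-substrate/one-product reversible Michaelis-Menten kinetics."""
    if km_s <= 0 or km_p <= 0:
        raise ParameterDomainError(
            f"reversible_michaelis_menten requires km_s, km_p > 0, "
            f"got {km_s}, {km_p}"
        )
    return (vmax_f * s / km_s - vmax_r * p / km_p) / (1.0 + s / km_s + p / km_p)


def hill(vmax: float, kd: float, n: float, s: float) -> float:
    """Hill kinetics v = vmax*S^n/(kd^n + S^n); n = 1 recovers Michaelis-Menten."""
    if kd <= 0 or n <= 0:
        raise ParameterDomainError(f"hill requires kd > 0 and n > 0, got kd={kd}, n={n}")
    if s < 0 and not float(n).is_integer():
        raise ParameterDomainError(
            f"hill with non-integer n={n} is undefined for S={s} < 0"
        )
    sn = s**n
    return vmax * sn / (kd**n + sn)


# ---------------------------------------------------------------------------
# catalog descriptors
# ---------------------------------------------------------------------------

#: number of kinetic parameters per catalog kind
CATALOG_KINDS = {
    "constant": 1,
    "mass_action": 1,
    "reversible_mass_action": 2,
    "michaelis_menten": 2,
    "reversible_michaelis_menten": 4,
    "hill": 3,
}


@dataclass(frozen=True)
class RateLawDescriptor:
    """Structural description of a catalog rate law bound to a reaction."""

    kind: str
    parameter_names: tuple[str, ...]
    substrate_count: int
    product_count: int
    reversible: bool

    def __post_init__(self) -> None:
        if self.kind not in CATALOG_KINDS:
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        expected = CATALOG_KINDS[self.kind]
        if len(self.parameter_names) != expected:
            raise ValueError(
                f"{self.kind} takes {expected} parameters, "
                f"got {len(self.parameter_names)}"
            )
        if self.reversible != self.kind.startswith("reversible_"):
            raise ValueError(
                f"reversible flag must mirror the kind; {self.kind} "
                f"with reversible={self.reversible}"
            )


@dataclass(frozen=True)
class RateLaw:
    """A catalog law bound to named parameters, substrates and products.

    Instances are callable with values in ``args`` order (kinetic parameters
    first, then substrates, then products) and know how to render themselves
    symbolically for SBML export and catalog recognition.
    """

    kind: str = field(init=False, default="")
    parameters: tuple[str, ...] = ()
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()

    @property
    def descriptor(self) -> RateLawDescriptor:
        return RateLawDescriptor(
            kind=self.kind,
            parameter_names=self.parameters,
            substrate_count=len(self.substrates),
            product_count=len(self.products),
            reversible=self.kind.startswith("reversible_"),
        )

    @property
    def args(self) -> tuple[str, ...]:
        """Ordered argument names the bound callable expects."""
        return self.parameters + self.substrates + self.products

    @property
    def reversible(self) -> bool:
        return self.kind.startswith("reversible_")

    def __call__(self, *values: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def sympy_expr(self):
        """The law as a sympy expression in symbols named after ``args``."""
        import sympy

        return self._expr(*[sympy.Symbol(a) for a in self.args])

    def _expr(self, *syms):  # pragma: no cover - abstract
        raise NotImplementedError


def _law(kind: str):
    def deco(cls):
        cls.kind = kind
        return cls

    return deco


@_law("constant")
@dataclass(frozen=True)
class Constant(RateLaw):
    def __init__(self, k: str):
        object.__setattr__(self, "parameters", (k,))
        object.__setattr__(self, "substrates", ())
        object.__setattr__(self, "products", ())

    def __call__(self, k):
        return constant(k)

    def _expr(self, k):
        return k


@_law("mass_action")
@dataclass(frozen=True)
class MassAction(RateLaw):
    def __init__(self, k: str, substrates: Sequence[str]):
        object.__setattr__(self, "parameters", (k,))
        object.__setattr__(self, "substrates", tuple(substrates))
        object.__setattr__(self, "products", ())

    def __call__(self, k, *s):
        return mass_action(k, *s)

    def _expr(self, k, *s):
        return k * math.prod(s) if s else k


@_law("reversible_mass_action")
@dataclass(frozen=True)
class ReversibleMassAction(RateLaw):
    def __init__(self, kf: str, kr: str, substrates: Sequence[str], products: Sequence[str]):
        object.__setattr__(self, "parameters", (kf, kr))
        object.__setattr__(self, "substrates", tuple(substrates))
        object.__setattr__(self, "products", tuple(products))

    def __call__(self, kf, kr, *conc):
        ns = len(self.substrates)
        return reversible_mass_action(kf, kr, conc[:ns], conc[ns:])

    def _expr(self, kf, kr, *conc):
        ns = len(self.substrates)
        fwd = kf * math.prod(conc[:ns]) if conc[:ns] else kf
        bwd = kr * math.prod(conc[ns:]) if conc[ns:] else kr
        return fwd - bwd


@_law("michaelis_menten")
@dataclass(frozen=True)
class MichaelisMenten(RateLaw):
    def __init__(self, vmax: str, km: str, substrate: str):
        object.__setattr__(self, "parameters", (vmax, km))
        object.__setattr__(self, "substrates", (substrate,))
        object.__setattr__(self, "products", ())

    def __call__(self, vmax, km, s):
        return michaelis_menten(vmax, km, s)

    def _expr(self, vmax, km, s):
        return vmax * s / (km + s)


@_law("reversible_michaelis_menten")
@dataclass(frozen=True)
class ReversibleMichaelisMenten(RateLaw):
    def __init__(self, vmax_f: str, vmax_r: str, km_s: str, km_p: str,
                 substrate: str, product: str):
        object.__setattr__(self, "parameters", (vmax_f, vmax_r, km_s, km_p))
        object.__setattr__(self, "substrates", (substrate,))
        object.__setattr__(self, "products", (product,))

    def __call__(self, vf, vr, kms, kmp, s, p):
        return reversible_michaelis_menten(vf, vr, kms, kmp, s, p)

    def _expr(self, vf, vr, kms, kmp, s, p):
        return (vf * s / kms - vr * p / kmp) / (1 + s / kms + p / kmp)


@_law("hill")
@dataclass(frozen=True)
class Hill(RateLaw):
    def __init__(self, vmax: str, kd: str, n: str, substrate: str):
        object.__setattr__(self, "parameters", (vmax, kd, n))
        object.__setattr__(self, "substrates", (substrate,))
        object.__setattr__(self, "products", ())

    def __call__(self, vmax, kd, n, s):
        return hill(vmax, kd, n, s)

    def _expr(self, vmax, kd, n, s):
        return vmax * s**n / (kd**n + s**n)


#: kind -> catalog class, used by SBML import to rebuild laws
LAW_CLASSES = {
    "constant": Constant,
    "mass_action": MassAction,
    "reversible_mass_action": ReversibleMassAction,
    "michaelis_menten": MichaelisMenten,
    "reversible_michaelis_menten": ReversibleMichaelisMenten,
    "hill": Hill,
}
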