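"""Expansion of a kinetic model into its isotope-label-specific version.

A compound with N labellable atoms has 2**N isotopomers, named
``base + "__" + pattern`` where the pattern is a binary string whose leftmost
character is atom 0 ('1' = labelled).  Given per-reaction atom transition
maps, every mapped reaction is expanded into one variant per combination of
substrate labelling patterns.

Rate partitioning.  Each variant's rate is the base rate evaluated at the
*total* concentrations, multiplied for every labelled substrate by the
fraction of that substrate pool in the chosen isotopomer:

    v_variant = v_base(totals) * prod_s  [s__pattern] / [s_total]

Under the well-mixed assumption this is exact for arbitrary kinetics, not
just mass action, and the variants of one reaction always sum to the base
rate — so the expanded model's totals track the base model's trajectories
identically.  A variant rate is defined as 0 whenever a required total is 0.

Mapped reactions must be irreversible; reversible reactions are to be split
into two opposing irreversible steps by the caller so that each direction
carries an explicit atom map.  Reactions in which a labelled compound appears
on both sides are rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import Model, Reaction
from .errors import LabelMappingError, UnknownSymbolError

#: separator between a compound name and its labelling pattern
PATTERN_SEP = "__"

#: one substrate's atom map: substrate atom index -> (product, product atom index)
AtomMap = Mapping[int, tuple[str, int]]


@dataclass
class LabelMapping:
    """Atom transition maps driving the isotopomer expansion.

    Attributes
    ----------
    labelled_compounds
        compound -> number of labellable atoms N (N >= 1).
    transitions
        reaction -> list of (substrate, atom map) pairs, one per labelled
        substrate.  An empty atom map marks a pure efflux of that substrate
        (label leaves the system).
    influx_patterns
        reaction -> (produced compound, fixed label pattern), for reactions
        that introduce labelled material without labelled substrates.
    """

    labelled_compounds: dict[str, int]
    transitions: dict[str, list[tuple[str, AtomMap]]] = field(default_factory=dict)
    influx_patterns: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, n in self.labelled_compounds.items():
            if n < 1:
                raise LabelMappingError(
                    f"compound {compound!r}: atom count must be >= 1, got {n}"
                )
        for rxn, entries in self.transitions.items():
            targets: dict[tuple[str, int], tuple[str, int]] = {}
            for substrate, amap in entries:
                if substrate not in self.labelled_compounds:
                    raise LabelMappingError(
                        f"reaction {rxn!r}: substrate {substrate!r} is not a "
                        f"labelled compound"
                    )
                n_sub = self.labelled_compounds[substrate]
                for j, (product, m) in amap.items():
                    if not 0 <= j < n_sub:
                        raise LabelMappingError(
                            f"reaction {rxn!r}: atom index {j} out of range "
                            f"for {substrate!r} (N={n_sub})"
                        )
                    if product not in self.labelled_compounds:
                        raise LabelMappingError(
                            f"reaction {rxn!r}: product {product!r} is not a "
                            f"labelled compound"
                        )
                    n_prod = self.labelled_compounds[product]
                    if not 0 <= m < n_prod:
                        raise LabelMappingError(
                            f"reaction {rxn!r}: product atom index {m} out of "
                            f"range for {product!r} (N={n_prod})"
                        )
                    key = (product, m)
                    if key in targets:
                        raise LabelMappingError(
                            f"reaction {rxn!r}: product atom {product}.{m} "
                            f"receives more than one source atom"
                        )
                    targets[key] = (substrate, j)
        for rxn, (compound, pattern) in self.influx_patterns.items():
            if compound not in self.labelled_compounds:
                raise LabelMappingError(
                    f"influx {rxn!r}: {compound!r} is not a labelled compound"
                )
            n = self.labelled_compounds[compound]
            if len(pattern) != n or set(pattern) - {"0", "1"}:
                raise LabelMappingError(
                    f"influx {rxn!r}: pattern {pattern!r} is not a binary "
                    f"string of length {n}"
                )


def label_variants(compound: str, n: int) -> list[str]:
    """All 2**n isotopomer names of a compound, lexicographic by pattern."""
    if n < 1:
        raise ValueError(f"atom count must be >= 1, got {n}")
    return [
        compound + PATTERN_SEP + "".join(bits)
        for bits in itertools.product("01", repeat=n)
    ]


def _patterns(n: int) -> list[str]:
    return ["".join(bits) for bits in itertools.product("01", repeat=n)]


def isotopomer_name(compound: str, pattern: str) -> str:
    return compound + PATTERN_SEP + pattern


def apply_transition(
    pattern: str,
    atom_map: AtomMap,
    product_sizes: Mapping[str, int],
) -> dict[str, str]:
    """Propagate one substrate's labelling pattern through its atom map.

    Returns product -> pattern; product atoms not sourced by the map default
    to unlabelled ('0').
    """
    out = {p: ["0"] * product_sizes[p] for p in {p for p, _ in atom_map.values()}}
    for j, (product, m) in atom_map.items():
        if not 0 <= j < len(pattern):
            raise LabelMappingError(
                f"atom index {j} out of range for pattern {pattern!r}"
            )
        out[product][m] = pattern[j]
    return {p: "".join(bits) for p, bits in out.items()}


def _merge_product_patterns(
    per_substrate: Sequence[Mapping[str, str]], product_sizes: Mapping[str, int]
) -> dict[str, str]:
    """Combine contributions from several substrates into final patterns."""
    merged: dict[str, list[str]] = {}
    for contrib in per_substrate:
        for product, pattern in contrib.items():
            bits = merged.setdefault(product, ["0"] * product_sizes[product])
            for m, ch in enumerate(pattern):
                if ch == "1":
                    bits[m] = "1"
    return {p: "".join(bits) for p, bits in merged.items()}


def expand_label_model(base: Model, mapping: LabelMapping) -> Model:
    """Expand a base model into its label-specific version.

    Every labelled compound is replaced by its 2**N isotopomers and every
    mapped reaction by one variant per combination of substrate patterns.
    Unlabelled compounds and unmapped reactions are copied verbatim; a
    reaction that touches a labelled compound but has no mapping is an error
    because it would break total-mass bookkeeping.
    """
    for compound in mapping.labelled_compounds:
        if compound not in base.compounds:
            raise UnknownSymbolError(f"labelled compound {compound!r} not in model")
    mapped = set(mapping.transitions) | set(mapping.influx_patterns)
    for name in mapped:
        if name not in base.reactions:
            raise UnknownSymbolError(f"mapped reaction {name!r} not in model")
    for name, rxn in base.reactions.items():
        touches = set(rxn.stoichiometry) & set(mapping.labelled_compounds)
        if touches and name not in mapped:
            raise LabelMappingError(
                f"reaction {name!r} involves labelled compounds "
                f"{sorted(touches)} but has no transition or influx entry"
            )

    sizes = mapping.labelled_compounds
    expanded = Model(parameters=base.parameters)
    for dp_name, dp in base.derived_parameters.items():
        expanded.add_derived_parameter(dp_name, dp.fn, dp.args)
    for compound in base.compounds:
        if compound in sizes:
            expanded.add_compounds(label_variants(compound, sizes[compound]))
        else:
            expanded.add_compound(compound)

    for name, rxn in base.reactions.items():
        if name in mapping.transitions:
            _expand_mapped_reaction(expanded, rxn, mapping)
        elif name in mapping.influx_patterns:
            _expand_influx_reaction(expanded, rxn, mapping)
        else:
            expanded.add_reaction(
                name,
                rxn.rate_law if rxn.rate_law is not None else rxn.fn,
                stoichiometry=dict(rxn.stoichiometry),
                args=rxn.args,
                modifiers=rxn.modifiers,
                reversible=rxn.reversible,
            )
    return expanded


def _variant_arg_layout(rxn: Reaction, sizes: Mapping[str, int]):
    """Expand labelled-compound args into isotopomer blocks.

    Returns (new_args, layout) where layout entries are either
    ('scalar', index) or ('total', start, stop) per base argument, in order.
    """
    new_args: list[str] = []
    layout: list[tuple] = []
    for a in rxn.args:
        if a in sizes:
            variants = label_variants(a, sizes[a])
            layout.append(("total", len(new_args), len(new_args) + len(variants), a))
            new_args.extend(variants)
        else:
            layout.append(("scalar", len(new_args)))
            new_args.append(a)
    return new_args, layout


def _expand_mapped_reaction(expanded: Model, rxn: Reaction,
                            mapping: LabelMapping) -> None:
    sizes = mapping.labelled_compounds
    if rxn.reversible:
        raise LabelMappingError(
            f"reaction {rxn.name!r} is reversible; split it into two "
            f"irreversible reactions before mapping atom transitions"
        )
    entries = mapping.transitions[rxn.name]
    substrates = [s for s, _ in entries]
    for s in substrates:
        coeff = rxn.stoichiometry.get(s)
        if coeff != -1:
            raise LabelMappingError(
                f"reaction {rxn.name!r}: labelled substrate {s!r} must have "
                f"stoichiometric coefficient -1, got {coeff}"
            )
    products_touched = {
        p for _, amap in entries for p, _ in amap.values()
    }
    both_sides = products_touched & set(substrates)
    if both_sides:
        raise LabelMappingError(
            f"reaction {rxn.name!r}: compounds {sorted(both_sides)} appear on "
            f"both sides; such reactions are not supported"
        )
    for p in products_touched:
        coeff = rxn.stoichiometry.get(p)
        if coeff != 1:
            raise LabelMappingError(
                f"reaction {rxn.name!r}: labelled product {p!r} must have "
                f"stoichiometric coefficient +1, got {coeff}"
            )
    # labelled compounds in the stoichiometry must be accounted for
    stray = (set(rxn.stoichiometry) & set(sizes)) - set(substrates) - products_touched
    # products that receive no atoms (fully unlabelled) still need expansion:
    unsourced_products = {
        p for p in stray if rxn.stoichiometry[p] > 0
    }
    stray -= unsourced_products
    if stray:
        raise LabelMappingError(
            f"reaction {rxn.name!r}: labelled compounds {sorted(stray)} are "
            f"consumed without an atom map entry"
        )

    new_args, layout = _variant_arg_layout(rxn, sizes)
    # make sure every labelled substrate's isotopomers are available to the
    # rate, even if the base rate never read that substrate
    for s in substrates:
        if not any(entry[0] == "total" and entry[3] == s for entry in layout):
            variants = label_variants(s, sizes[s])
            start = len(new_args)
            new_args.extend(variants)
            layout.append(("extra_total", start, start + len(variants), s))

    total_slices = {
        entry[3]: (entry[1], entry[2])
        for entry in layout
        if entry[0] in ("total", "extra_total")
    }
    base_layout = [e for e in layout if e[0] != "extra_total"]
    base_fn = rxn.fn

    product_sizes = {p: sizes[p] for p in products_touched}

    pattern_sets = [_patterns(sizes[s]) for s in substrates]
    for combo in itertools.product(*pattern_sets):
        variant_name = rxn.name + PATTERN_SEP + "_".join(combo)
        stoich = {
            c: v for c, v in rxn.stoichiometry.items()
            if c not in substrates and c not in products_touched
        }
        for p in unsourced_products:
            stoich.pop(p, None)
        per_substrate = []
        fraction_spec: list[tuple[int, int, int]] = []   # (start, stop, offset)
        for s, pattern, (_, amap) in zip(substrates, combo, entries):
            iso = isotopomer_name(s, pattern)
            stoich[iso] = stoich.get(iso, 0.0) - 1.0
            start, stop = total_slices[s]
            fraction_spec.append((start, stop, int(pattern, 2)))
            per_substrate.append(
                apply_transition(pattern, amap, product_sizes)
            )
        merged = _merge_product_patterns(per_substrate, product_sizes)
        for p in products_touched:
            pattern = merged.get(p, "0" * sizes[p])
            iso = isotopomer_name(p, pattern)
            stoich[iso] = stoich.get(iso, 0.0) + 1.0
        for p in unsourced_products:
            iso = isotopomer_name(p, "0" * sizes[p])
            stoich[iso] = stoich.get(iso, 0.0) + rxn.stoichiometry[p]

        fn = _make_variant_rate(base_fn, base_layout, fraction_spec)
        modifiers = tuple(
            a for a in new_args
            if a not in stoich and a != "time"
            and a in expanded.compounds
        ) + tuple(m for m in rxn.modifiers if m == "time")
        expanded.add_reaction(
            variant_name,
            fn,
            stoichiometry={c: v for c, v in stoich.items() if v != 0},
            args=tuple(new_args),
            modifiers=modifiers,
            reversible=False,
        )


def _make_variant_rate(base_fn, base_layout, fraction_spec):
    def variant_rate(*vals):
        base_vals = []
        for entry in base_layout:
            if entry[0] == "scalar":
                base_vals.append(vals[entry[1]])
            else:
                base_vals.append(sum(vals[entry[1]:entry[2]]))
        factor = 1.0
        for start, stop, offset in fraction_spec:
            total = sum(vals[start:stop])
            if total <= 0.0:
                return 0.0
            factor *= vals[start + offset] / total
        return base_fn(*base_vals) * factor

    return variant_rate


def _expand_influx_reaction(expanded: Model, rxn: Reaction,
                            mapping: LabelMapping) -> None:
    sizes = mapping.labelled_compounds
    compound, pattern = mapping.influx_patterns[rxn.name]
    coeff = rxn.stoichiometry.get(compound)
    if coeff is None or coeff <= 0:
        raise LabelMappingError(
            f"influx {rxn.name!r} must produce {compound!r}"
        )
    other_labelled = (set(rxn.stoichiometry) | set(rxn.args)) & set(sizes)
    if other_labelled - {compound}:
        raise LabelMappingError(
            f"influx {rxn.name!r} touches labelled compounds "
            f"{sorted(other_labelled - {compound})}; use a transition entry"
        )
    if compound in rxn.args:
        raise LabelMappingError(
            f"influx {rxn.name!r}: rate reading the produced labelled "
            f"compound is not supported"
        )
    stoich = {c: v for c, v in rxn.stoichiometry.items() if c != compound}
    stoich[isotopomer_name(compound, pattern)] = coeff
    expanded.add_reaction(
        rxn.name,
        rxn.rate_law if rxn.rate_law is not None else rxn.fn,
        stoichiometry=stoich,
        args=rxn.args,
        modifiers=rxn.modifiers,
        reversible=rxn.reversible,
    )


# -- readback ---------------------------------------------------------------

def total_concentration(
    state: Mapping[str, float], compound: str, mapping: LabelMapping
) -> float:
    """Sum of all isotopomer concentrations of a labelled compound."""
    if compound not in mapping.labelled_compounds:
        raise UnknownSymbolError(f"{compound!r} was not labelled in the expansion")
    return float(sum(
        state[v] for v in label_variants(compound, mapping.labelled_compounds[compound])
    ))


def label_fraction(
    state: Mapping[str, float], compound: str, atom_index: int,
    mapping: LabelMapping,
) -> float:
    """Fraction of the pool labelled at one atom position (0/0 -> 0)."""
    if compound not in mapping.labelled_compounds:
        raise UnknownSymbolError(f"{compound!r} was not labelled in the expansion")
    n = mapping.labelled_compounds[compound]
    if not 0 <= atom_index < n:
        raise ValueError(f"atom index {atom_index} out of range for N={n}")
    total = 0.0
    labelled = 0.0
    for pattern in _patterns(n):
        x = float(state[isotopomer_name(compound, pattern)])
        total += x
        if pattern[atom_index] == "1":
            labelled += x
    return labelled / total if total > 0 else 0.0


def expand_initial_state(
    base_state: Mapping[str, float], mapping: LabelMapping
) -> dict[str, float]:
    """Initial state for the expanded model: all pools start unlabelled."""
    out: dict[str, float] = {}
    for compound, value in base_state.items():
        if compound in mapping.labelled_compounds:
            n = mapping.labelled_compounds[compound]
            for pattern in _patterns(n):
                out[isotopomer_name(compound, pattern)] = (
                    float(value) if pattern == "0" * n else 0.0
                )
        else:
            out[compound] = float(value)
    return out
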