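"""SBML Level 3 subset import and export.

Export covers models built entirely from the catalog rate laws: compounds
become species in a single default compartment of size 1, parameters become
global parameters, derived parameters become assignment rules, and each
reaction carries its law's canonical content-MathML kinetic law together with
a small annotation naming the catalog kind (which lets import rebuild the
exact law object instead of a generic expression).  Reactions with arbitrary
user callables cannot be serialised and raise :class:`SbmlExportError`.

Import is the inverse on that subset, and additionally accepts any kinetic
law whose MathML uses the arithmetic operators below, compiling it into a
generic expression rate — such models simulate fine but cannot be
re-exported unless rebuilt from the catalog (a deliberate asymmetry).
Constructs outside the subset (events, delays, algebraic and rate rules,
function definitions, multiple compartments) raise
:class:`UnsupportedConstructError` listing every offender.

Derived parameters are serialised by tracing the Python function with
symbolic arguments, so any derived parameter built from ordinary arithmetic
exports faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import sympy
from lxml import etree

from .core import Model, TIME
from .errors import EmptyModelError, SbmlExportError, UnsupportedConstructError
from .ratelaws import LAW_CLASSES, RateLaw

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
RATELAW_NS = "urn:kinmod:ratelaw"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"

COMPARTMENT_ID = "default"


@dataclass
class SbmlSubsetReport:
    """What an import encountered: construct names in and out of the subset."""

    supported: list[str] = field(default_factory=list)
    unsupported: list[str] = field(default_factory=list)
    #: species initialConcentration values, for convenience
    initial_concentrations: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.unsupported


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _num(value: float) -> str:
    return repr(float(value))


# ---------------------------------------------------------------------------
# content MathML construction
# ---------------------------------------------------------------------------

def _ci(parent, name: str):
    el = etree.SubElement(parent, _q(MATHML_NS, "ci"))
    el.text = f" {name} "
    return el


def _cn(parent, value) -> None:
    el = etree.SubElement(parent, _q(MATHML_NS, "cn"))
    if float(value).is_integer():
        el.set("type", "integer")
        el.text = f" {int(value)} "
    else:
        el.text = f" {float(value)!r} "


def _apply(parent, op: str):
    ap = etree.SubElement(parent, _q(MATHML_NS, "apply"))
    etree.SubElement(ap, _q(MATHML_NS, op))
    return ap


def _sympy_to_mathml(parent, expr) -> None:
    """Serialise an arithmetic sympy expression as content MathML."""
    if isinstance(expr, sympy.Symbol):
        _ci(parent, expr.name)
    elif isinstance(expr, sympy.Integer):
        _cn(parent, int(expr))
    elif isinstance(expr, sympy.Rational):
        ap = _apply(parent, "divide")
        _cn(ap, int(expr.p))
        _cn(ap, int(expr.q))
    elif isinstance(expr, sympy.Float):
        _cn(parent, float(expr))
    elif isinstance(expr, sympy.Add):
        ap = _apply(parent, "plus")
        for term in expr.args:
            _sympy_to_mathml(ap, term)
    elif isinstance(expr, sympy.Mul):
        num, den = expr.as_numer_denom()
        if den != 1:
            ap = _apply(parent, "divide")
            _sympy_to_mathml(ap, num)
            _sympy_to_mathml(ap, den)
        else:
            ap = _apply(parent, "times")
            for factor in expr.args:
                _sympy_to_mathml(ap, factor)
    elif isinstance(expr, sympy.Pow):
        base, exponent = expr.args
        ap = _apply(parent, "power")
        _sympy_to_mathml(ap, base)
        _sympy_to_mathml(ap, exponent)
    elif expr is sympy.exp or isinstance(expr, sympy.exp):
        ap = _apply(parent, "exp")
        _sympy_to_mathml(ap, expr.args[0])
    elif isinstance(expr, sympy.log):
        ap = _apply(parent, "ln")
        _sympy_to_mathml(ap, expr.args[0])
    else:
        raise SbmlExportError(
            f"cannot serialise expression node {expr!r} to MathML"
        )


def _trace_symbolically(fn, args: tuple[str, ...]):
    """Run a Python function on sympy symbols to recover its expression."""
    symbols = [sympy.Symbol(a) for a in args]
    try:
        expr = fn(*symbols)
        return sympy.sympify(expr)
    except Exception as exc:
        raise SbmlExportError(
            f"function {getattr(fn, '__name__', fn)!r} cannot be traced "
            f"symbolically for SBML export: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_sbml_model(
    model: Model,
    path: str | Path | None = None,
    initial_state: Mapping[str, float] | None = None,
    model_id: str = "model",
) -> str:
    """Serialise a catalog-built model to an SBML Level 3 document.

    Parameters
    ----------
    model
        Every reaction must be catalog-built (carry a rate-law descriptor).
    path
        Optional file to write; the XML string is returned either way.
    initial_state
        Species initial concentrations (default 0 for every compound).
    """
    custom = [n for n, r in model.reactions.items() if r.rate_law is None]
    if custom:
        raise SbmlExportError(
            f"reactions {custom} use custom rate callables; only "
            f"catalog-built models can be exported"
        )
    if not model.compounds:
        raise EmptyModelError("cannot export a model without compounds")
    initial_state = dict(initial_state or {})

    nsmap = {None: SBML_NS}
    root = etree.Element(_q(SBML_NS, "sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mdl = etree.SubElement(root, _q(SBML_NS, "model"))
    mdl.set("id", model_id)

    comps = etree.SubElement(mdl, _q(SBML_NS, "listOfCompartments"))
    comp = etree.SubElement(comps, _q(SBML_NS, "compartment"))
    comp.set("id", COMPARTMENT_ID)
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")
    comp.set("constant", "true")

    species_list = etree.SubElement(mdl, _q(SBML_NS, "listOfSpecies"))
    for compound in model.compounds:
        sp = etree.SubElement(species_list, _q(SBML_NS, "species"))
        sp.set("id", compound)
        sp.set("compartment", COMPARTMENT_ID)
        sp.set("initialConcentration", _num(initial_state.get(compound, 0.0)))
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")
        _annotate(sp, model, compound)

    params_list = etree.SubElement(mdl, _q(SBML_NS, "listOfParameters"))
    for name, value in model.parameters.items():
        par = etree.SubElement(params_list, _q(SBML_NS, "parameter"))
        par.set("id", name)
        par.set("value", _num(value))
        par.set("constant", "true")
        _annotate(par, model, name)
    resolved = model._resolved_parameters()
    for name in model.derived_parameters:
        par = etree.SubElement(params_list, _q(SBML_NS, "parameter"))
        par.set("id", name)
        par.set("value", _num(resolved[name]))
        par.set("constant", "false")

    if model.derived_parameters:
        rules = etree.SubElement(mdl, _q(SBML_NS, "listOfRules"))
        for name, dp in model.derived_parameters.items():
            rule = etree.SubElement(rules, _q(SBML_NS, "assignmentRule"))
            rule.set("variable", name)
            math = etree.SubElement(
                rule, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS}
            )
            _sympy_to_mathml(math, _trace_symbolically(dp.fn, dp.args))

    rxn_list = etree.SubElement(mdl, _q(SBML_NS, "listOfReactions"))
    for name, rxn in model.reactions.items():
        el = etree.SubElement(rxn_list, _q(SBML_NS, "reaction"))
        el.set("id", name)
        el.set("reversible", "true" if rxn.reversible else "false")
        _annotate(el, model, name)
        reactants = {c: -v for c, v in rxn.stoichiometry.items() if v < 0}
        products = {c: v for c, v in rxn.stoichiometry.items() if v > 0}
        if reactants:
            lst = etree.SubElement(el, _q(SBML_NS, "listOfReactants"))
            for c, v in reactants.items():
                ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                ref.set("species", c)
                ref.set("stoichiometry", _num(v))
                ref.set("constant", "true")
        if products:
            lst = etree.SubElement(el, _q(SBML_NS, "listOfProducts"))
            for c, v in products.items():
                ref = etree.SubElement(lst, _q(SBML_NS, "speciesReference"))
                ref.set("species", c)
                ref.set("stoichiometry", _num(v))
                ref.set("constant", "true")
        modifiers = [m for m in rxn.modifiers if m != TIME]
        if modifiers:
            lst = etree.SubElement(el, _q(SBML_NS, "listOfModifiers"))
            for c in modifiers:
                ref = etree.SubElement(
                    lst, _q(SBML_NS, "modifierSpeciesReference")
                )
                ref.set("species", c)
        kin = etree.SubElement(el, _q(SBML_NS, "kineticLaw"))
        ann = etree.SubElement(kin, _q(SBML_NS, "annotation"))
        law: RateLaw = rxn.rate_law
        tag = etree.SubElement(
            ann, _q(RATELAW_NS, "ratelaw"), nsmap={None: RATELAW_NS}
        )
        tag.set("kind", law.kind)
        tag.set("parameters", " ".join(law.parameters))
        tag.set("substrates", " ".join(law.substrates))
        tag.set("products", " ".join(law.products))
        math = etree.SubElement(
            kin, _q(MATHML_NS, "math"), nsmap={None: MATHML_NS}
        )
        _sympy_to_mathml(math, law.sympy_expr())

    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()
    if path is not None:
        Path(path).write_text(doc)
    return doc


def _annotate(element, model: Model, component: str) -> None:
    """MIRIAM-style RDF annotation plus display name, when metadata exists."""
    ann = model.metadata.get(component)
    if ann is None:
        return
    if ann.common_name:
        element.set("name", ann.common_name)
    if not ann.identifiers:
        return
    el = etree.SubElement(element, _q(SBML_NS, "annotation"))
    rdf = etree.SubElement(
        el, _q(RDF_NS, "RDF"), nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS}
    )
    desc = etree.SubElement(rdf, _q(RDF_NS, "Description"))
    desc.set(_q(RDF_NS, "about"), f"#{component}")
    is_el = etree.SubElement(desc, _q(BQBIOL_NS, "is"))
    bag = etree.SubElement(is_el, _q(RDF_NS, "Bag"))
    for uri in ann.identifiers:
        li = etree.SubElement(bag, _q(RDF_NS, "li"))
        li.set(_q(RDF_NS, "resource"), uri)


# ---------------------------------------------------------------------------
# MathML compilation (import)
# ---------------------------------------------------------------------------

_BINARY_OPS = {
    "plus": lambda args: sum(args),
    "times": lambda args: _prod(args),
    "divide": lambda args: args[0] / args[1],
    "power": lambda args: args[0] ** args[1],
}


def _prod(args):
    out = 1.0
    for a in args:
        out = out * a
    return out


def _mathml_children(node):
    return [c for c in node if isinstance(c.tag, str)]


def compile_mathml(math_element):
    """Compile a content-MathML tree into ``(fn, arg_names)``.

    ``arg_names`` lists every ``<ci>`` symbol in first-appearance order, with
    the SBML time csymbol mapped to the reserved token ``"time"``.  The
    returned function takes the argument values positionally.
    """
    import math as pymath

    arg_names: list[str] = []

    def build(node):
        tag = etree.QName(node).localname
        if tag == "math":
            children = _mathml_children(node)
            if len(children) != 1:
                raise UnsupportedConstructError(["math with multiple roots"])
            return build(children[0])
        if tag == "ci":
            name = node.text.strip()
            if name not in arg_names:
                arg_names.append(name)
            idx = arg_names.index(name)
            return lambda vals: vals[idx]
        if tag == "csymbol":
            url = node.get("definitionURL", "")
            if url.endswith("/time"):
                if TIME not in arg_names:
                    arg_names.append(TIME)
                idx = arg_names.index(TIME)
                return lambda vals: vals[idx]
            if url.endswith("/delay"):
                raise UnsupportedConstructError(["delay"])
            raise UnsupportedConstructError([f"csymbol {url}"])
        if tag == "cn":
            kind = node.get("type", "real")
            if kind == "rational":
                parts = node.text.split()  # "p <sep/> q" handled below
                num = float(parts[0])
                sep = node.find(_q(MATHML_NS, "sep"))
                den = float(sep.tail.strip()) if sep is not None else 1.0
                value = num / den
            elif kind == "e-notation":
                sep = node.find(_q(MATHML_NS, "sep"))
                mant = float(node.text.strip())
                expo = float(sep.tail.strip()) if sep is not None else 0.0
                value = mant * 10.0**expo
            else:
                value = float(node.text.strip())
            return lambda vals: value
        if tag == "apply":
            children = _mathml_children(node)
            op = etree.QName(children[0]).localname
            operands = [build(c) for c in children[1:]]
            if op == "minus":
                if len(operands) == 1:
                    f = operands[0]
                    return lambda vals: -f(vals)
                a, b = operands
                return lambda vals: a(vals) - b(vals)
            if op in _BINARY_OPS:
                combine = _BINARY_OPS[op]
                return lambda vals: combine([f(vals) for f in operands])
            if op == "exp":
                f = operands[0]
                return lambda vals: pymath.exp(f(vals))
            if op == "ln":
                f = operands[0]
                return lambda vals: pymath.log(f(vals))
            if op == "root":
                f = operands[-1]
                return lambda vals: pymath.sqrt(f(vals))
            raise UnsupportedConstructError([f"MathML operator {op}"])
        raise UnsupportedConstructError([f"MathML element {tag}"])

    body = build(math_element)

    def fn(*values):
        return body(values)

    return fn, tuple(arg_names)


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def _scan_unsupported(mdl) -> list[str]:
    found = []
    for tag, label in [
        ("listOfEvents", "event"),
        ("listOfConstraints", "constraint"),
        ("listOfFunctionDefinitions", "functionDefinition"),
        ("listOfInitialAssignments", "initialAssignment"),
    ]:
        el = mdl.find(_q(SBML_NS, tag))
        if el is not None and len(el):
            found.append(label)
    rules = mdl.find(_q(SBML_NS, "listOfRules"))
    species_ids = {
        sp.get("id")
        for sp in mdl.iterfind(
            f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"
        )
    }
    if rules is not None:
        for rule in rules:
            tag = etree.QName(rule).localname
            if tag == "algebraicRule":
                found.append("algebraicRule")
            elif tag == "rateRule":
                found.append("rateRule")
            elif tag == "assignmentRule":
                if rule.get("variable") in species_ids:
                    found.append("assignmentRule on species")
    compartments = mdl.findall(
        f"{_q(SBML_NS, 'listOfCompartments')}/{_q(SBML_NS, 'compartment')}"
    )
    if len(compartments) > 1:
        found.append("multiple compartments")
    for el in mdl.iter(_q(MATHML_NS, "csymbol")):
        if el.get("definitionURL", "").endswith("/delay"):
            found.append("delay")
    return found


def build_model_from_sbml(source: str | Path) -> tuple[Model, SbmlSubsetReport]:
    """Parse an SBML document into a model plus a subset report.

    ``source`` may be a path or an XML string.  Kinetic laws carrying the
    catalog annotation are rebuilt as catalog rate laws; anything else is
    compiled from its MathML into a generic expression rate (readable but not
    re-exportable).
    """
    text = str(source)
    if "<" not in text:
        text = Path(source).read_text()
    root = etree.fromstring(text.encode())
    if etree.QName(root).localname != "sbml":
        raise ValueError("not an SBML document")
    mdl = root.find(_q(SBML_NS, "model"))
    if mdl is None:
        raise EmptyModelError("document has no <model> element")

    report = SbmlSubsetReport()
    report.unsupported = _scan_unsupported(mdl)
    if report.unsupported:
        raise UnsupportedConstructError(report.unsupported)

    species = mdl.findall(
        f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"
    )
    if not species:
        raise EmptyModelError("document declares no species")

    model = Model()
    for sp in species:
        sid = sp.get("id")
        model.add_compound(sid)
        report.initial_concentrations[sid] = float(
            sp.get("initialConcentration", "0") or 0.0
        )
        if sp.get("name"):
            model.annotate(sid, common_name=sp.get("name"))
    report.supported.append("species")

    derived_ids = set()
    rules = mdl.find(_q(SBML_NS, "listOfRules"))
    if rules is not None:
        derived_ids = {r.get("variable") for r in rules}
    for par in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfParameters')}/{_q(SBML_NS, 'parameter')}"
    ):
        pid = par.get("id")
        if pid in derived_ids:
            continue
        model.add_parameter(pid, float(par.get("value", "0") or 0.0))
    report.supported.append("parameters")

    if rules is not None:
        for rule in rules:
            name = rule.get("variable")
            math = rule.find(_q(MATHML_NS, "math"))
            fn, args = compile_mathml(math)
            model.add_derived_parameter(name, fn, args)
        report.supported.append("assignmentRules")

    for rxn in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"
    ):
        rid = rxn.get("id")
        reversible = rxn.get("reversible", "false") == "true"
        stoich: dict[str, float] = {}
        for ref in rxn.iterfind(
            f"{_q(SBML_NS, 'listOfReactants')}/{_q(SBML_NS, 'speciesReference')}"
        ):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) - float(
                ref.get("stoichiometry", "1")
            )
        for ref in rxn.iterfind(
            f"{_q(SBML_NS, 'listOfProducts')}/{_q(SBML_NS, 'speciesReference')}"
        ):
            stoich[ref.get("species")] = stoich.get(ref.get("species"), 0.0) + float(
                ref.get("stoichiometry", "1")
            )
        stoich = {c: v for c, v in stoich.items() if v != 0}
        kin = rxn.find(_q(SBML_NS, "kineticLaw"))
        if kin is None:
            raise UnsupportedConstructError([f"reaction {rid} without kineticLaw"])
        tag = kin.find(f"{_q(SBML_NS, 'annotation')}/{_q(RATELAW_NS, 'ratelaw')}")
        if tag is not None and tag.get("kind") in LAW_CLASSES:
            rate = _rebuild_catalog_law(tag)
            args = None
            modifiers = tuple(
                a for a in rate.args
                if a in model.compounds and a not in stoich
            )
        else:
            math = kin.find(_q(MATHML_NS, "math"))
            rate, args = compile_mathml(math)
            modifiers = tuple(
                a for a in args
                if (a in model.compounds and a not in stoich) or a == TIME
            )
        model.add_reaction(
            rid, rate, stoichiometry=stoich, args=args,
            modifiers=modifiers, reversible=reversible,
        )
    report.supported.append("reactions")
    return model, report


def _rebuild_catalog_law(tag) -> RateLaw:
    kind = tag.get("kind")
    params = tuple(tag.get("parameters", "").split())
    substrates = tuple(tag.get("substrates", "").split())
    products = tuple(tag.get("products", "").split())
    cls = LAW_CLASSES[kind]
    if kind == "constant":
        return cls(*params)
    if kind == "mass_action":
        return cls(params[0], substrates)
    if kind == "reversible_mass_action":
        return cls(params[0], params[1], substrates, products)
    if kind == "michaelis_menten":
        return cls(params[0], params[1], substrates[0])
    if kind == "reversible_michaelis_menten":
        return cls(*params, substrates[0], products[0])
    if kind == "hill":
        return cls(*params, substrates[0])
    raise ValueError(f"unknown catalog kind {kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

def validate_sbml(document: str) -> list[str]:
    """Structural validation of an SBML L3 document against the subset.

    Checks well-formedness, required attributes, id uniqueness and that every
    symbol referenced by species references and kinetic laws resolves.
    Returns a list of problems; an empty list means the document is valid.
    """
    problems: list[str] = []
    try:
        root = etree.fromstring(document.encode())
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if etree.QName(root).localname != "sbml":
        return ["root element is not <sbml>"]
    if root.get("level") != "3":
        problems.append("level attribute is not 3")
    mdl = root.find(_q(SBML_NS, "model"))
    if mdl is None:
        return problems + ["missing <model>"]

    ids: list[str] = []
    compartments = set()
    for comp in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfCompartments')}/{_q(SBML_NS, 'compartment')}"
    ):
        ids.append(comp.get("id"))
        compartments.add(comp.get("id"))
        if comp.get("constant") is None:
            problems.append(f"compartment {comp.get('id')}: missing 'constant'")
    species_ids = set()
    for sp in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfSpecies')}/{_q(SBML_NS, 'species')}"
    ):
        sid = sp.get("id")
        ids.append(sid)
        species_ids.add(sid)
        if sp.get("compartment") not in compartments:
            problems.append(f"species {sid}: unresolved compartment")
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if sp.get(attr) is None:
                problems.append(f"species {sid}: missing {attr!r}")
    parameter_ids = set()
    for par in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfParameters')}/{_q(SBML_NS, 'parameter')}"
    ):
        ids.append(par.get("id"))
        parameter_ids.add(par.get("id"))
        if par.get("constant") is None:
            problems.append(f"parameter {par.get('id')}: missing 'constant'")
    symbols = species_ids | parameter_ids | compartments
    for rxn in mdl.iterfind(
        f"{_q(SBML_NS, 'listOfReactions')}/{_q(SBML_NS, 'reaction')}"
    ):
        rid = rxn.get("id")
        ids.append(rid)
        if rxn.get("reversible") is None:
            problems.append(f"reaction {rid}: missing 'reversible'")
        for ref in rxn.iter(
            _q(SBML_NS, "speciesReference"),
            _q(SBML_NS, "modifierSpeciesReference"),
        ):
            if ref.get("species") not in species_ids:
                problems.append(
                    f"reaction {rid}: unresolved species "
                    f"{ref.get('species')!r}"
                )
        for ci in rxn.iter(_q(MATHML_NS, "ci")):
            name = (ci.text or "").strip()
            if name not in symbols:
                problems.append(f"reaction {rid}: unresolved symbol {name!r}")
    seen = set()
    for i in ids:
        if i in seen:
            problems.append(f"duplicate id {i!r}")
        seen.add(i)
    return problems
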