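"""SBML Level 2 Version 4 import/export for mass-action networks.

The exchange format covers exactly what the model class represents: species
with initial amounts, global rate-constant parameters, irreversible
mass-action reactions (kinetic law = product of one parameter and the
reactant/modifier amounts), boundary species standing for the external
inputs (with a zeroing event encoding the irradiation pulse), and a model
annotation block that carries observables, constraints, module tags and
fixed-parameter ids so a write/load cycle is lossless.

Kinetic laws that are not plain products raise ``UnsupportedKineticsError``;
structurally broken documents raise ``SBMLParseError`` naming the offending
element.
"""

from __future__ import annotations

from lxml import etree

from .network import (
    ConstraintDef,
    InputSignal,
    NetworkModel,
    ObservableDef,
    ReactionDef,
    SpeciesDef,
)

__all__ = ["load_model", "write_model", "SBMLParseError", "UnsupportedKineticsError"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANN_NS = "urn:senesim:model-annotation"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS
_A = "{%s}" % ANN_NS


class SBMLParseError(ValueError):
    """The document is not structurally valid SBML L2V4 for this package."""


class UnsupportedKineticsError(SBMLParseError):
    """A kinetic law is not a plain mass-action product."""


def _sid(name: str) -> str:
    """Make a valid SBML SId from a display name."""
    out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in name)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


def write_model(model: NetworkModel, path: str) -> None:
    """Serialise the network to SBML Level 2 Version 4."""
    root = etree.Element(_S + "sbml", nsmap={None: SBML_NS}, level="2", version="4")
    mdl = etree.SubElement(root, _S + "model", id=_sid(model.name), name=model.name)

    ann = etree.SubElement(mdl, _S + "annotation")
    meta = etree.SubElement(ann, _A + "model", nsmap={"ssm": ANN_NS})
    obs_el = etree.SubElement(meta, _A + "observables")
    for o in model.observables:
        etree.SubElement(
            obs_el,
            _A + "observable",
            id=o.id,
            name=o.name,
            species=" ".join(o.component_species),
            scale=repr(o.scaling_factor),
        )
    con_el = etree.SubElement(meta, _A + "constraints")
    for c in model.constraints:
        etree.SubElement(
            con_el,
            _A + "constraint",
            id=c.id,
            smaller=c.expression[0],
            larger=c.expression[1],
            strength=repr(c.penalty_strength),
        )
    etree.SubElement(meta, _A + "fixedParameters").text = " ".join(model.fixed_parameter_ids)

    comps = etree.SubElement(mdl, _S + "listOfCompartments")
    etree.SubElement(comps, _S + "compartment", id="cell", size="1")

    sp_el = etree.SubElement(mdl, _S + "listOfSpecies")
    for s in model.species:
        el = etree.SubElement(
            sp_el,
            _S + "species",
            id=s.id,
            name=s.name,
            compartment="cell",
            initialAmount=repr(float(s.initial_amount)),
        )
        sann = etree.SubElement(el, _S + "annotation")
        etree.SubElement(
            sann,
            _A + "speciesInfo",
            nsmap={"ssm": ANN_NS},
            module=s.module_tag,
            **({"pair": s.conserved_pair_id} if s.conserved_pair_id else {}),
        )
    for sig in model.inputs:
        el = etree.SubElement(
            sp_el,
            _S + "species",
            id=_sid(sig.name),
            name=sig.name,
            compartment="cell",
            initialAmount=repr(float(sig.level)),
            boundaryCondition="true",
        )
        sann = etree.SubElement(el, _S + "annotation")
        etree.SubElement(
            sann,
            _A + "inputInfo",
            nsmap={"ssm": ANN_NS},
            kind=sig.kind,
            **(
                {"pulseStart": repr(sig.pulse_start), "pulseWidth": repr(sig.pulse_width)}
                if sig.kind == "pulse"
                else {}
            ),
        )

    par_el = etree.SubElement(mdl, _S + "listOfParameters")
    for r in model.reactions:
        etree.SubElement(par_el, _S + "parameter", id=r.id, value=repr(float(r.rate_constant)))

    rx_el = etree.SubElement(mdl, _S + "listOfReactions")
    input_sids = {sig.name: _sid(sig.name) for sig in model.inputs}
    for r in model.reactions:
        el = etree.SubElement(rx_el, _S + "reaction", id="r_" + r.id, reversible="false")
        if r.name:
            el.set("name", r.name)
        if r.reactants:
            lst = etree.SubElement(el, _S + "listOfReactants")
            for sid, sto in r.reactants.items():
                etree.SubElement(lst, _S + "speciesReference", species=sid, stoichiometry=str(sto))
        if r.products:
            lst = etree.SubElement(el, _S + "listOfProducts")
            for sid, sto in r.products.items():
                etree.SubElement(lst, _S + "speciesReference", species=sid, stoichiometry=str(sto))
        if r.modifiers:
            lst = etree.SubElement(el, _S + "listOfModifiers")
            for mid in dict.fromkeys(r.modifiers):
                etree.SubElement(
                    lst, _S + "modifierSpeciesReference", species=input_sids.get(mid, mid)
                )
        kin = etree.SubElement(el, _S + "kineticLaw")
        math = etree.SubElement(kin, _M + "math", nsmap={None: MATHML_NS})
        factors = [r.id]
        for sid, sto in r.reactants.items():
            factors.extend([sid] * sto)
        for mid in r.modifiers:
            factors.append(input_sids.get(mid, mid))
        if len(factors) == 1:
            ci = etree.SubElement(math, _M + "ci")
            ci.text = factors[0]
        else:
            ap = etree.SubElement(math, _M + "apply")
            etree.SubElement(ap, _M + "times")
            for f in factors:
                ci = etree.SubElement(ap, _M + "ci")
                ci.text = f
    # pulse inputs: an event zeroing the boundary species at the pulse end
    pulses = [sig for sig in model.inputs if sig.kind == "pulse"]
    if pulses:
        ev_el = etree.SubElement(mdl, _S + "listOfEvents")
        for sig in pulses:
            ev = etree.SubElement(ev_el, _S + "event", id="end_" + _sid(sig.name))
            trig = etree.SubElement(ev, _S + "trigger")
            math = etree.SubElement(trig, _M + "math", nsmap={None: MATHML_NS})
            ap = etree.SubElement(math, _M + "apply")
            etree.SubElement(ap, _M + "geq")
            csym = etree.SubElement(
                ap, _M + "csymbol", definitionURL="http://www.sbml.org/sbml/symbols/time"
            )
            csym.text = "t"
            cn = etree.SubElement(ap, _M + "cn")
            cn.text = repr(sig.pulse_start + sig.pulse_width)
            asg_l = etree.SubElement(ev, _S + "listOfEventAssignments")
            asg = etree.SubElement(asg_l, _S + "eventAssignment", variable=_sid(sig.name))
            math = etree.SubElement(asg, _M + "math", nsmap={None: MATHML_NS})
            cn = etree.SubElement(math, _M + "cn")
            cn.text = "0"

    etree.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _parse_product(math_el, rxn_id: str) -> list[str]:
    """Extract the ordered ci factors of a plain-product kinetic law."""
    children = [c for c in math_el if isinstance(c.tag, str)]
    if len(children) != 1:
        raise UnsupportedKineticsError(f"reaction {rxn_id}: kinetic law is not a single expression")
    expr = children[0]
    if expr.tag == _M + "ci":
        return [expr.text.strip()]
    if expr.tag != _M + "apply":
        raise UnsupportedKineticsError(f"reaction {rxn_id}: unsupported kinetic law element {expr.tag}")
    ops = [c for c in expr if isinstance(c.tag, str)]
    if not ops or ops[0].tag != _M + "times":
        raise UnsupportedKineticsError(f"reaction {rxn_id}: kinetic law is not a mass-action product")
    factors = []
    for c in ops[1:]:
        if c.tag != _M + "ci":
            raise UnsupportedKineticsError(
                f"reaction {rxn_id}: non-symbol factor {c.tag} in kinetic law"
            )
        factors.append(c.text.strip())
    return factors


def load_model(path: str) -> NetworkModel:
    """Load a mass-action network from an SBML Level 2 Version 4 file."""
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise SBMLParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _S + "sbml":
        raise SBMLParseError(f"root element is {root.tag!r}, expected SBML level 2 version 4")
    mdl = root.find(_S + "model")
    if mdl is None:
        raise SBMLParseError("missing <model> element")

    # annotations
    observables, constraints, fixed = [], [], ()
    meta = mdl.find(f"{_S}annotation/{_A}model")
    if meta is not None:
        for o in meta.findall(f"{_A}observables/{_A}observable"):
            observables.append(
                ObservableDef(
                    o.get("id"),
                    o.get("name"),
                    tuple(o.get("species").split()),
                    float(o.get("scale", "1.0")),
                )
            )
        for c in meta.findall(f"{_A}constraints/{_A}constraint"):
            constraints.append(
                ConstraintDef(c.get("id"), (c.get("smaller"), c.get("larger")), float(c.get("strength", "1")))
            )
        fp = meta.find(f"{_A}fixedParameters")
        if fp is not None and fp.text:
            fixed = tuple(fp.text.split())

    species, inputs = [], []
    sid_to_input = {}
    for el in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        sid = el.get("id")
        if sid is None:
            raise SBMLParseError("species without id")
        amt = float(el.get("initialAmount", "0"))
        if el.get("boundaryCondition") == "true":
            info = el.find(f"{_S}annotation/{_A}inputInfo")
            kind = info.get("kind") if info is not None else "constant"
            sig = InputSignal(
                el.get("name", sid),
                kind,
                amt,
                float(info.get("pulseStart", "0")) if info is not None and kind == "pulse" else 0.0,
                float(info.get("pulseWidth", "0")) if info is not None and kind == "pulse" else 0.0,
            )
            inputs.append(sig)
            sid_to_input[sid] = sig.name
        else:
            info = el.find(f"{_S}annotation/{_A}speciesInfo")
            species.append(
                SpeciesDef(
                    sid,
                    el.get("name", sid),
                    amt,
                    info.get("module") if info is not None else "IIS-mTOR",
                    info.get("pair") if info is not None else None,
                )
            )

    params = {}
    for el in mdl.findall(f"{_S}listOfParameters/{_S}parameter"):
        params[el.get("id")] = float(el.get("value", "0"))

    reactions = []
    for el in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = el.get("id", "")
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for ref in el.findall(f"{_S}listOfReactants/{_S}speciesReference"):
            reactants[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        for ref in el.findall(f"{_S}listOfProducts/{_S}speciesReference"):
            products[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
        kin = el.find(f"{_S}kineticLaw")
        if kin is None:
            raise SBMLParseError(f"reaction {rid}: missing kinetic law")
        math = kin.find(f"{_M}math")
        if math is None:
            raise SBMLParseError(f"reaction {rid}: kinetic law without math")
        factors = _parse_product(math, rid)
        pid = None
        consumed: list[str] = []
        for f in factors:
            if f in params and pid is None:
                pid = f
            else:
                consumed.append(f)
        if pid is None:
            raise UnsupportedKineticsError(f"reaction {rid}: no rate-constant parameter in kinetic law")
        # reactant factors (with stoichiometry) must appear; the rest are modifiers
        remaining = list(consumed)
        for sid, sto in reactants.items():
            for _ in range(sto):
                if sid not in remaining:
                    raise UnsupportedKineticsError(
                        f"reaction {rid}: kinetic law misses reactant {sid}"
                    )
                remaining.remove(sid)
        modifiers = tuple(sid_to_input.get(f, f) for f in remaining)
        reactions.append(
            ReactionDef(pid, reactants, products, modifiers, params[pid], el.get("name", ""))
        )

    return NetworkModel(
        species,
        reactions,
        inputs,
        observables,
        constraints,
        fixed,
        name=mdl.get("name", mdl.get("id", "model")),
    )
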