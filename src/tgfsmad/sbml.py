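"""SBML Level 3 import/export for mass-action reaction networks.

The writer emits SBML L3V2 with every kinetic law rendered as an explicit
mass-action MathML product (rate constant times reactant and modifier
species), constant species exported with boundary-condition semantics,
and a package annotation recording the relative-concentration convention
(cytoplasm/nucleus volume ratio and medium/cell volume ratio) so a round
trip does not silently rescale nuclear species.

The reader accepts exactly that mass-action subset (Level 3; Level 2
documents with the same structure also parse) and rejects any other rate
law -- Michaelis-Menten, Hill or arbitrary MathML -- with a clear error,
because the simulation core is strictly mass action.
"""

from __future__ import annotations

from lxml import etree

from .models import ModelVariant, ALL_EFFECTS, MODEL_EFFECTS
from .network import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
SBML_L2_NS_PREFIX = "http://www.sbml.org/sbml/level2"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://github.com/tgfsmad/annotations"

_COMPARTMENT_IDS = ("extracellular", "cytoplasm", "early_endosome",
                    "caveolae", "nucleus")


class SBMLError(ValueError):
    """Malformed or unsupported SBML content."""


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


# -- export ----------------------------------------------------------------

def sbml_export(network: ReactionNetwork, path: str) -> None:
    """Write a network as SBML L3V2 with mass-action kinetic laws."""
    nsmap = {None: SBML_NS, "tgfsmad": ANNOT_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, _q("model"))
    model.set("id", network.name.replace(" ", "_"))
    model.set("timeUnits", "minute")

    annot = etree.SubElement(model, _q("annotation"))
    conv = etree.SubElement(annot, _q("concentrationConvention", ANNOT_NS))
    conv.set("nuclearSpecies", "cytoplasm-volume-relative")
    conv.set("volumeRatio", repr(network.volume_ratio))
    conv.set("mediumRatio", repr(network.medium_ratio))

    comps = etree.SubElement(model, _q("listOfCompartments"))
    for cid in _COMPARTMENT_IDS:
        c = etree.SubElement(comps, _q("compartment"))
        c.set("id", cid)
        c.set("size", "1")  # relative-concentration convention
        c.set("constant", "true")

    species_el = etree.SubElement(model, _q("listOfSpecies"))
    for sp in network.species:
        s = etree.SubElement(species_el, _q("species"))
        s.set("id", sp.name)
        s.set("compartment", sp.compartment)
        s.set("initialConcentration", repr(sp.initial_concentration))
        s.set("hasOnlySubstanceUnits", "false")
        s.set("boundaryCondition", "true" if sp.constant else "false")
        s.set("constant", "false")

    params_el = etree.SubElement(model, _q("listOfParameters"))
    for name, value in network.parameters.items():
        p = etree.SubElement(params_el, _q("parameter"))
        p.set("id", name)
        p.set("value", repr(value))
        p.set("constant", "true")

    rxns_el = etree.SubElement(model, _q("listOfReactions"))
    for rxn in network.reactions:
        r = etree.SubElement(rxns_el, _q("reaction"))
        r.set("id", rxn.name)
        r.set("reversible", "false")
        if rxn.reactants:
            lo = etree.SubElement(r, _q("listOfReactants"))
            for name in sorted(set(rxn.reactants)):
                ref = etree.SubElement(lo, _q("speciesReference"))
                ref.set("species", name)
                ref.set("stoichiometry", repr(float(
                    rxn.reactants.count(name))))
                ref.set("constant", "true")
        if rxn.products:
            lo = etree.SubElement(r, _q("listOfProducts"))
            for name in sorted(set(rxn.products)):
                ref = etree.SubElement(lo, _q("speciesReference"))
                ref.set("species", name)
                ref.set("stoichiometry", repr(float(
                    rxn.products.count(name))))
                ref.set("constant", "true")
        if rxn.modifiers:
            lo = etree.SubElement(r, _q("listOfModifiers"))
            for name in rxn.modifiers:
                ref = etree.SubElement(lo, _q("modifierSpeciesReference"))
                ref.set("species", name)
        kl = etree.SubElement(r, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS),
                                nsmap={None: MATHML_NS})
        factors = [rxn.rate_constant, *rxn.reactants, *rxn.modifiers]
        if len(factors) == 1:
            ci = etree.SubElement(math, _q("ci", MATHML_NS))
            ci.text = factors[0]
        else:
            apply_el = etree.SubElement(math, _q("apply", MATHML_NS))
            etree.SubElement(apply_el, _q("times", MATHML_NS))
            for f in factors:
                ci = etree.SubElement(apply_el, _q("ci", MATHML_NS))
                ci.text = f

    tree = etree.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


# -- import ----------------------------------------------------------------

def _strip(tag: str) -> str:
    return tag.split("}", 1)[-1]


def _math_factors(math) -> list[str]:
    """Flatten a mass-action MathML expression into its ci factors.

    Accepts a bare <ci>, or <apply><times/> over <ci> elements; anything
    else (power, divide, plus, cn constants, piecewise ...) is rejected.
    """
    children = [c for c in math if not isinstance(c, etree._Comment)]
    if len(children) != 1:
        raise SBMLError("kinetic law must contain a single expression")
    node = children[0]
    tag = _strip(node.tag)
    if tag == "ci":
        return [node.text.strip()]
    if tag != "apply":
        raise SBMLError(f"unsupported kinetic law element <{tag}>")
    ops = list(node)
    if not ops or _strip(ops[0].tag) != "times":
        raise SBMLError(
            f"unsupported rate law operator "
            f"<{_strip(ops[0].tag) if ops else 'empty'}>; only explicit "
            f"mass-action products are supported"
        )
    factors = []
    for el in ops[1:]:
        if _strip(el.tag) != "ci":
            raise SBMLError(
                f"unsupported factor <{_strip(el.tag)}> in rate law; only "
                f"parameter and species identifiers are allowed"
            )
        factors.append(el.text.strip())
    return factors


def sbml_import(path: str) -> ReactionNetwork:
    """Read an SBML file with mass-action kinetic laws into a network."""
    tree = etree.parse(path)
    root = tree.getroot()
    ns = root.nsmap.get(None, "")
    if not (ns == SBML_NS or ns.startswith(SBML_L2_NS_PREFIX)):
        raise SBMLError(f"not an SBML level 2/3 document (namespace {ns!r})")
    model = root.find(_q("model", ns))
    if model is None:
        raise SBMLError("no <model> element")

    volume_ratio, medium_ratio = 2.3, 2000.0
    conv = model.find(f"{_q('annotation', ns)}/"
                      f"{_q('concentrationConvention', ANNOT_NS)}")
    if conv is not None:
        volume_ratio = float(conv.get("volumeRatio", volume_ratio))
        medium_ratio = float(conv.get("mediumRatio", medium_ratio))

    species = []
    for s in model.findall(f"{_q('listOfSpecies', ns)}/{_q('species', ns)}"):
        species.append(Species(
            name=s.get("id"),
            compartment=s.get("compartment", "cytoplasm"),
            initial_concentration=float(s.get("initialConcentration",
                                              "0") or 0.0),
            constant=s.get("boundaryCondition", "false") == "true",
        ))

    params = ParameterSet()
    for p in model.findall(f"{_q('listOfParameters', ns)}/"
                           f"{_q('parameter', ns)}"):
        params[p.get("id")] = float(p.get("value", "0"))

    reactions = []
    for r in model.findall(f"{_q('listOfReactions', ns)}/"
                           f"{_q('reaction', ns)}"):
        rid = r.get("id")

        def refs(tag: str) -> list[str]:
            out = []
            for ref in r.findall(f"{_q(tag, ns)}/"
                                 f"{_q('speciesReference', ns)}"):
                stoich = float(ref.get("stoichiometry", "1"))
                if abs(stoich - round(stoich)) > 1e-9:
                    raise SBMLError(f"reaction {rid}: non-integer "
                                    f"stoichiometry {stoich}")
                out.extend([ref.get("species")] * int(round(stoich)))
            return out

        reactants = tuple(refs("listOfReactants"))
        products = tuple(refs("listOfProducts"))
        modifiers = tuple(
            ref.get("species") for ref in
            r.findall(f"{_q('listOfModifiers', ns)}/"
                      f"{_q('modifierSpeciesReference', ns)}"))
        math = r.find(f"{_q('kineticLaw', ns)}/{_q('math', MATHML_NS)}")
        if math is None:
            raise SBMLError(f"reaction {rid}: missing kinetic law")
        factors = _math_factors(math)
        k_candidates = [f for f in factors if f in params]
        if len(k_candidates) != 1:
            raise SBMLError(
                f"reaction {rid}: rate law must reference exactly one "
                f"parameter (found {k_candidates})"
            )
        k = k_candidates[0]
        law_species = sorted(f for f in factors if f != k)
        if law_species != sorted((*reactants, *modifiers)):
            raise SBMLError(
                f"reaction {rid}: rate law factors {law_species} do not "
                f"match the mass-action product of reactants and modifiers"
            )
        reactions.append(Reaction(rid, reactants, products, k, modifiers))

    net = ReactionNetwork(
        name=model.get("id", "imported"), species=species,
        reactions=reactions, parameters=params,
        volume_ratio=volume_ratio, medium_ratio=medium_ratio,
    )
    findings = net.validate()
    if findings:
        raise SBMLError(f"imported network is inconsistent: {findings}")
    return net


def import_model_variant(path: str) -> ModelVariant:
    """Import an SBML file and wrap it as a model variant.

    The effect flags are inferred from the reaction names when they match
    the package's own export; otherwise the variant carries an empty flag
    set and every parameter is treated as fixed.
    """
    net = sbml_import(path)
    rxn_names = {r.name for r in net.reactions}
    flags = set()
    for flag in ALL_EFFECTS:
        from .models import _effect_block
        _, block = _effect_block(flag)
        if any(b.name in rxn_names for b in block):
            flags.add(flag)
    mid = net.name.replace("Model_", "").replace("Model ", "")
    if mid not in MODEL_EFFECTS:
        mid = "imported"
    return ModelVariant(
        model_id=mid, effects=frozenset(flags), network=net,
        estimated_parameters=[], fixed_parameters=list(net.parameters),
    )
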