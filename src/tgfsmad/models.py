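"""The TGF-beta/Smad model family: a shared pathway skeleton plus
toggleable negative-regulation blocks.

Every variant (Models 1-8, S1, S2, S3) shares a skeleton of receptor
trafficking (ligand binding at the surface, internalisation into the early
endosome and caveolae, recycling, constitutive receptor turnover),
Smad2 phosphorylation by the endosomal ligand-receptor complex (LRC),
homomeric and heteromeric Smad complex formation at a common rate, and
nucleocytoplasmic shuttling with faster import for Smad complexes than for
monomers.  Receptor trafficking follows the Vilar/Klipp model lineage;
Smad shuttling follows the Schmierer model lineage; the
``ReactionNetwork.reaction_sources`` map records the provenance of each
reaction (skeleton lineage vs. effect block).

Negative-regulation blocks, matching the model x effect matrix:

====== ======== ============ ========= ========= =============
Model  Dephos.  ReceptorDeg  PSmadDeg  Turnover  PPM1A stab.
====== ======== ============ ========= ========= =============
1      +        -            -         -         -
2      +        +            -         -         -
3      -        +            -         -         -
4      -        -            +         -         -
5      +        +            +         -         -
6      +        -            +         -         -
7      +        -            +         +         -
8      +        -            +         +         +
====== ======== ============ ========= ========= =============

S1 = Model 5 plus dynamic I-Smad (Smad7) feedback; S2 replaces PPM1A
stabilisation with Smad-complex-induced PPM1A expression; S3 is the
minimal PPM1A-stabilisation variant (dephosphorylation + stabilisation).

Units are minutes and nM throughout.  Nuclear species are stored as
cytoplasm-volume-relative concentrations; extracellular ligand as a
cell-volume-relative amount (see :mod:`tgfsmad.network`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    NetworkConfigError,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    conserved_totals,
)

# -- effect flags ----------------------------------------------------------

DEPHOSPHORYLATION = "DEPHOSPHORYLATION"
RECEPTOR_DEGRADATION = "RECEPTOR_DEGRADATION"
PSMAD_DEGRADATION = "PSMAD_DEGRADATION"
ENDOGENOUS_SMAD_TURNOVER = "ENDOGENOUS_SMAD_TURNOVER"
PPM1A_STABILIZATION = "PPM1A_STABILIZATION"
ISMAD_FEEDBACK = "ISMAD_FEEDBACK"
PPM1A_EXPRESSION = "PPM1A_EXPRESSION"

ALL_EFFECTS = (
    DEPHOSPHORYLATION,
    RECEPTOR_DEGRADATION,
    PSMAD_DEGRADATION,
    ENDOGENOUS_SMAD_TURNOVER,
    PPM1A_STABILIZATION,
    ISMAD_FEEDBACK,
    PPM1A_EXPRESSION,
)

#: Model id -> effect-flag pattern (the model x effect matrix).
MODEL_EFFECTS: dict[str, frozenset[str]] = {
    "1": frozenset({DEPHOSPHORYLATION}),
    "2": frozenset({DEPHOSPHORYLATION, RECEPTOR_DEGRADATION}),
    "3": frozenset({RECEPTOR_DEGRADATION}),
    "4": frozenset({PSMAD_DEGRADATION}),
    "5": frozenset({DEPHOSPHORYLATION, RECEPTOR_DEGRADATION, PSMAD_DEGRADATION}),
    "6": frozenset({DEPHOSPHORYLATION, PSMAD_DEGRADATION}),
    "7": frozenset({DEPHOSPHORYLATION, PSMAD_DEGRADATION,
                    ENDOGENOUS_SMAD_TURNOVER}),
    "8": frozenset({DEPHOSPHORYLATION, PSMAD_DEGRADATION,
                    ENDOGENOUS_SMAD_TURNOVER, PPM1A_STABILIZATION}),
    "S1": frozenset({DEPHOSPHORYLATION, RECEPTOR_DEGRADATION,
                     PSMAD_DEGRADATION, ISMAD_FEEDBACK}),
    "S2": frozenset({DEPHOSPHORYLATION, PSMAD_DEGRADATION,
                     ENDOGENOUS_SMAD_TURNOVER, PPM1A_EXPRESSION}),
    "S3": frozenset({DEPHOSPHORYLATION, PPM1A_STABILIZATION}),
}

MODEL_IDS = tuple(MODEL_EFFECTS)

# -- totals / observables --------------------------------------------------

TOTAL_SMAD2_NM = 571.43   # relative total Smad2 in HaCaT, nM
TOTAL_SMAD4_NM = 1333.33  # relative total Smad4 in HaCaT, nM
TOTAL_PTEN_NM = 250.0     # total PTEN (conserved in the stabilisation block)
SMAD7_NM = 100.0          # buffered Smad7 level in HaCaT


# -- default rate constants ------------------------------------------------

def default_parameters() -> ParameterSet:
    """Shared default rate constants for every variant.

    Trafficking and shuttling rates are carried over from the prior-model
    lineage (tagged ``fixed_prior_model``); effect-block rates are the
    package defaults used as the ground truth for synthetic data and as
    starting values for estimation (tagged ``estimated``).
    """
    lit = {
        # receptor production/turnover (uniform basal turnover keeps the
        # stimulated total receptor pool at its production/degradation
        # balance, matching the flat measured T1R)
        "kprod_T1R": 0.002,   # nM/min
        "kprod_T2R": 0.004,   # nM/min
        "kdeg_R": 0.002,      # 1/min, basal turnover of receptors and LRC
        # ligand binding (relative-ligand units; medium volume folded in)
        "ka_ligand": 0.01,    # 1/(nM min)
        "ka_receptor": 1.0,   # 1/(nM min)
        # trafficking
        "ki_EE": 0.33,        # 1/min, internalisation to early endosome
        "ki_cave": 0.33,      # 1/min, internalisation to caveolae
        "kr_EE": 0.033,       # 1/min, endosomal recycling (ligand degraded)
        "kr_cave": 0.03,      # 1/min, caveolar recycling of intact LRC
        # Smad phosphorylation by endosomal LRC
        "kphos": 0.04,        # 1/(nM min)
        # complex formation (homomeric and heteromeric at the same rate)
        "kon_smad": 0.006,    # 1/(nM min)
        "koff_smad": 0.25,    # 1/min
        # nucleocytoplasmic shuttling (relative-concentration convention)
        "kin_S2": 0.156,      # 1/min
        "kex_S2": 0.34,       # 1/min
        "kin_S4": 0.08,       # 1/min
        "kex_S4": 0.26,       # 1/min
        "kin_complex": 0.9,   # 1/min, faster than monomer import
    }
    est = {
        # negative-regulation blocks
        "kdephos": 0.4,          # 1/min, implicit PPM1A dephosphorylation
        "klid": 1e-4,            # 1/(nM min), Smad7-driven caveolar LRC deg.
        "kdeg_pSmad2": 0.005,    # 1/min, Smurf2 route on nuclear P-Smad2
        "kdeg_S2": 0.004,        # 1/min, endogenous R-Smad turnover
        "ksyn_S2": 0.004 * TOTAL_SMAD2_NM,  # nM/min, tied to kdeg_S2
        # explicit PPM1A block (Models 8, S2, S3)
        "ksyn_PPM1A": 1.5,       # nM/min
        "kdeg_PPM1A": 0.05,      # 1/min, free PPM1A only
        "kimp_PPM1A": 1.0,       # 1/min, fast nuclear import
        "kon_cat": 0.035,        # 1/(nM min), phosphatase-substrate binding
        "koff_cat": 1.0,         # 1/min
        "kcat_dephos": 2.0,      # 1/min, catalytic dephosphorylation
        # PTEN stabilisation (Models 8, S3)
        "kon_pten": 0.005,       # 1/(nM min), pSmad2-PTEN association
        "koff_pten": 1.0,        # 1/min
        "kon_ternary": 3.0,      # 1/(nM min), + PPM1A -> ternary complex
        "koff_ternary": 0.1,     # 1/min
        "krel_ternary": 1.0,     # 1/min, release of PTEN:PPM1A
        "kimp_pp": 0.0015,       # 1/min, slow nuclear import of PTEN:PPM1A
        "kdiss_pp": 0.0005,      # 1/min, nuclear PTEN:PPM1A dissociation
        "kex_PTEN": 0.1,         # 1/min, nuclear PTEN export
        # PPM1A expression block (Model S2)
        "kinduce_PPM1A": 0.01,   # 1/(nM min) x [nuclear Smad complex]
        # I-Smad feedback block (Model S1)
        "kprod_S7": 0.05,        # 1/(nM min) x [nuclear Smad complex]
        "kdeg_S7": 0.005,        # 1/min
        "ka_S7_LRC": 0.001,      # 1/(nM min)
        "kdeph_LRC": 0.01,       # 1/min, inactivation releasing receptors
        "kdeg_S7LRC": 0.01,      # 1/min, degradation of the bound LRC
    }
    prov = {k: "fixed_prior_model" for k in lit}
    prov.update({k: "estimated" for k in est})
    return ParameterSet({**lit, **est}, prov)


# -- skeleton assembly -----------------------------------------------------

def _skeleton() -> tuple[list[Species], list[Reaction], dict[str, str]]:
    kin, kex = 0.156, 0.34
    kin4, kex4 = 0.08, 0.26
    s2c0 = TOTAL_SMAD2_NM * kex / (kin + kex)
    s2n0 = TOTAL_SMAD2_NM - s2c0
    s4c0 = TOTAL_SMAD4_NM * kex4 / (kin4 + kex4)
    s4n0 = TOTAL_SMAD4_NM - s4c0
    species = [
        Species("TGFB", "extracellular", 0.0),
        Species("T2R", "cytoplasm", 2.0),
        Species("T1R", "cytoplasm", 1.0),
        Species("TGFB_T2R", "cytoplasm", 0.0),
        Species("LRC_surf", "cytoplasm", 0.0),
        Species("LRC_EE", "early_endosome", 0.0),
        Species("LRC_cave", "caveolae", 0.0),
        Species("S2c", "cytoplasm", s2c0),
        Species("S2n", "nucleus", s2n0),
        Species("pS2c", "cytoplasm", 0.0),
        Species("pS2n", "nucleus", 0.0),
        Species("S4c", "cytoplasm", s4c0),
        Species("S4n", "nucleus", s4n0),
        Species("pS2_S4_c", "cytoplasm", 0.0),
        Species("pS2_S4_n", "nucleus", 0.0),
        Species("pS2_pS2_c", "cytoplasm", 0.0),
        Species("pS2_pS2_n", "nucleus", 0.0),
        Species("SMAD7", "cytoplasm", SMAD7_NM, constant=True),
    ]
    R = Reaction
    reactions = [
        # receptor production and basal turnover
        R("prod_T2R", (), ("T2R",), "kprod_T2R"),
        R("prod_T1R", (), ("T1R",), "kprod_T1R"),
        R("deg_T2R", ("T2R",), (), "kdeg_R"),
        R("deg_T1R", ("T1R",), (), "kdeg_R"),
        R("deg_TGFB_T2R", ("TGFB_T2R",), (), "kdeg_R"),
        R("deg_LRC_surf", ("LRC_surf",), (), "kdeg_R"),
        R("deg_LRC_EE", ("LRC_EE",), (), "kdeg_R"),
        R("deg_LRC_cave", ("LRC_cave",), (), "kdeg_R"),
        # ligand binding and LRC assembly
        R("bind_ligand", ("TGFB", "T2R"), ("TGFB_T2R",), "ka_ligand"),
        R("bind_T1R", ("TGFB_T2R", "T1R"), ("LRC_surf",), "ka_receptor"),
        # trafficking
        R("internalize_EE", ("LRC_surf",), ("LRC_EE",), "ki_EE"),
        R("internalize_cave", ("LRC_surf",), ("LRC_cave",), "ki_cave"),
        R("recycle_cave", ("LRC_cave",), ("LRC_surf",), "kr_cave"),
        R("recycle_EE", ("LRC_EE",), ("T1R", "T2R"), "kr_EE"),
        # phosphorylation by the endosomal LRC (catalytic modifier)
        R("phosphorylate_S2", ("S2c",), ("pS2c",), "kphos",
          modifiers=("LRC_EE",)),
        # complex formation/dissociation, cytoplasm
        R("assoc_hetero_c", ("pS2c", "S4c"), ("pS2_S4_c",), "kon_smad"),
        R("dissoc_hetero_c", ("pS2_S4_c",), ("pS2c", "S4c"), "koff_smad"),
        R("assoc_homo_c", ("pS2c", "pS2c"), ("pS2_pS2_c",), "kon_smad"),
        R("dissoc_homo_c", ("pS2_pS2_c",), ("pS2c", "pS2c"), "koff_smad"),
        # complex formation/dissociation, nucleus
        R("assoc_hetero_n", ("pS2n", "S4n"), ("pS2_S4_n",), "kon_smad"),
        R("dissoc_hetero_n", ("pS2_S4_n",), ("pS2n", "S4n"), "koff_smad"),
        R("assoc_homo_n", ("pS2n", "pS2n"), ("pS2_pS2_n",), "kon_smad"),
        R("dissoc_homo_n", ("pS2_pS2_n",), ("pS2n", "pS2n"), "koff_smad"),
        # nucleocytoplasmic shuttling
        R("import_S2", ("S2c",), ("S2n",), "kin_S2"),
        R("export_S2", ("S2n",), ("S2c",), "kex_S2"),
        R("import_pS2", ("pS2c",), ("pS2n",), "kin_S2"),
        R("export_pS2", ("pS2n",), ("pS2c",), "kex_S2"),
        R("import_S4", ("S4c",), ("S4n",), "kin_S4"),
        R("export_S4", ("S4n",), ("S4c",), "kex_S4"),
        R("import_hetero", ("pS2_S4_c",), ("pS2_S4_n",), "kin_complex"),
        R("import_homo", ("pS2_pS2_c",), ("pS2_pS2_n",), "kin_complex"),
    ]
    sources = {r.name: "skeleton:receptor-trafficking" for r in reactions[:14]}
    sources.update({r.name: "skeleton:smad-shuttling" for r in reactions[14:]})
    return species, reactions, sources


def _ppm1a_core(two_step_dephos: bool) -> tuple[list[Species], list[Reaction]]:
    """Explicit PPM1A pool: synthesis, degradation, fast nuclear import,
    and (optionally) two-step catalytic dephosphorylation."""
    species = [
        Species("PPM1A_c", "cytoplasm", 1.4),
        Species("PPM1A_n", "nucleus", 28.6),
    ]
    R = Reaction
    reactions = [
        R("syn_PPM1A", (), ("PPM1A_c",), "ksyn_PPM1A"),
        R("deg_PPM1A_c", ("PPM1A_c",), (), "kdeg_PPM1A"),
        R("deg_PPM1A_n", ("PPM1A_n",), (), "kdeg_PPM1A"),
        R("import_PPM1A", ("PPM1A_c",), ("PPM1A_n",), "kimp_PPM1A"),
    ]
    if two_step_dephos:
        species.append(Species("PPM1A_pS2_n", "nucleus", 0.0))
        reactions += [
            R("cat_bind", ("PPM1A_n", "pS2n"), ("PPM1A_pS2_n",), "kon_cat"),
            R("cat_unbind", ("PPM1A_pS2_n",), ("PPM1A_n", "pS2n"), "koff_cat"),
            R("cat_dephos", ("PPM1A_pS2_n",), ("PPM1A_n", "S2n"),
              "kcat_dephos"),
        ]
    return species, reactions


def _effect_block(flag: str) -> tuple[list[Species], list[Reaction]]:
    R = Reaction
    if flag == DEPHOSPHORYLATION:
        return [], [R("dephos_pS2n", ("pS2n",), ("S2n",), "kdephos")]
    if flag == RECEPTOR_DEGRADATION:
        return [], [R("lid_LRC_cave", ("LRC_cave",), (), "klid",
                      modifiers=("SMAD7",))]
    if flag == PSMAD_DEGRADATION:
        return [], [R("smurf_deg_pS2n", ("pS2n",), (), "kdeg_pSmad2")]
    if flag == ENDOGENOUS_SMAD_TURNOVER:
        return [], [
            R("syn_S2", (), ("S2c",), "ksyn_S2"),
            R("turnover_S2c", ("S2c",), (), "kdeg_S2"),
            R("turnover_S2n", ("S2n",), (), "kdeg_S2"),
            R("turnover_pS2c", ("pS2c",), (), "kdeg_S2"),
            R("turnover_pS2n", ("pS2n",), (), "kdeg_S2"),
        ]
    if flag == PPM1A_STABILIZATION:
        species, reactions = _ppm1a_core(two_step_dephos=True)
        species += [
            Species("PTEN_c", "cytoplasm", TOTAL_PTEN_NM),
            Species("PTEN_n", "nucleus", 0.0),
            Species("pS2_PTEN_c", "cytoplasm", 0.0),
            Species("pS2_PTEN_PPM1A_c", "cytoplasm", 0.0),
            Species("PTEN_PPM1A_c", "cytoplasm", 0.0),
            Species("PTEN_PPM1A_n", "nucleus", 0.0),
            Species("PTEN_PPM1A_pS2_n", "nucleus", 0.0),
        ]
        reactions += [
            # phospho-Smad2 scaffolds PTEN-PPM1A association in the cytosol
            R("pten_bind_pS2", ("pS2c", "PTEN_c"), ("pS2_PTEN_c",),
              "kon_pten"),
            R("pten_unbind_pS2", ("pS2_PTEN_c",), ("pS2c", "PTEN_c"),
              "koff_pten"),
            R("ternary_assoc", ("pS2_PTEN_c", "PPM1A_c"),
              ("pS2_PTEN_PPM1A_c",), "kon_ternary"),
            R("ternary_dissoc", ("pS2_PTEN_PPM1A_c",),
              ("pS2_PTEN_c", "PPM1A_c"), "koff_ternary"),
            R("ternary_release", ("pS2_PTEN_PPM1A_c",),
              ("pS2c", "PTEN_PPM1A_c"), "krel_ternary"),
            # the PTEN-bound pool evades degradation; slow nuclear import
            R("import_PTEN_PPM1A", ("PTEN_PPM1A_c",), ("PTEN_PPM1A_n",),
              "kimp_pp"),
            R("dissoc_PTEN_PPM1A_n", ("PTEN_PPM1A_n",),
              ("PTEN_n", "PPM1A_n"), "kdiss_pp"),
            R("export_PTEN", ("PTEN_n",), ("PTEN_c",), "kex_PTEN"),
            # PTEN-bound PPM1A keeps its phosphatase activity
            R("cat_bind_pp", ("PTEN_PPM1A_n", "pS2n"),
              ("PTEN_PPM1A_pS2_n",), "kon_cat"),
            R("cat_unbind_pp", ("PTEN_PPM1A_pS2_n",),
              ("PTEN_PPM1A_n", "pS2n"), "koff_cat"),
            R("cat_dephos_pp", ("PTEN_PPM1A_pS2_n",),
              ("PTEN_PPM1A_n", "S2n"), "kcat_dephos"),
        ]
        return species, reactions
    if flag == PPM1A_EXPRESSION:
        species, reactions = _ppm1a_core(two_step_dephos=True)
        reactions += [
            R("induce_PPM1A_hetero", (), ("PPM1A_c",), "kinduce_PPM1A",
              modifiers=("pS2_S4_n",)),
            R("induce_PPM1A_homo", (), ("PPM1A_c",), "kinduce_PPM1A",
              modifiers=("pS2_pS2_n",)),
        ]
        return species, reactions
    if flag == ISMAD_FEEDBACK:
        species = [
            Species("S7LRC_EE", "early_endosome", 0.0),
            Species("S7LRC_cave", "caveolae", 0.0),
        ]
        reactions = [
            R("prod_S7_hetero", (), ("SMAD7",), "kprod_S7",
              modifiers=("pS2_S4_n",)),
            R("prod_S7_homo", (), ("SMAD7",), "kprod_S7",
              modifiers=("pS2_pS2_n",)),
            R("turnover_S7", ("SMAD7",), (), "kdeg_S7"),
            R("s7_bind_cave", ("SMAD7", "LRC_cave"), ("S7LRC_cave",),
              "ka_S7_LRC"),
            R("s7_bind_EE", ("SMAD7", "LRC_EE"), ("S7LRC_EE",), "ka_S7_LRC"),
            R("s7_dephos_cave", ("S7LRC_cave",), ("SMAD7", "T1R", "T2R"),
              "kdeph_LRC"),
            R("s7_dephos_EE", ("S7LRC_EE",), ("SMAD7", "T1R", "T2R"),
              "kdeph_LRC"),
            R("s7_deg_cave", ("S7LRC_cave",), ("SMAD7",), "kdeg_S7LRC"),
            R("s7_deg_EE", ("S7LRC_EE",), ("SMAD7",), "kdeg_S7LRC"),
        ]
        return species, reactions
    raise NetworkConfigError(f"unknown effect flag {flag!r}")


# -- observables -----------------------------------------------------------

def observable_weights(network: ReactionNetwork) -> dict[str, dict[str, float]]:
    """Stoichiometry-weighted species sums for the measured observables.

    P-Smad2 counts every phosphorylated-Smad2 copy in any compartment and
    complex (total-cell-lysate convention); the homomeric complex counts
    twice.
    """
    have = set(network.species_names)

    def pick(weights: dict[str, float]) -> dict[str, float]:
        return {k: v for k, v in weights.items() if k in have}

    psmad2 = pick({
        "pS2c": 1, "pS2n": 1, "pS2_S4_c": 1, "pS2_S4_n": 1,
        "pS2_pS2_c": 2, "pS2_pS2_n": 2,
        "pS2_PTEN_c": 1, "pS2_PTEN_PPM1A_c": 1,
        "PPM1A_pS2_n": 1, "PTEN_PPM1A_pS2_n": 1,
    })
    smad2 = dict(psmad2)
    smad2.update(pick({"S2c": 1, "S2n": 1}))
    out = {
        "PSmad2_total": psmad2,
        "Smad2_total": smad2,
        "Smad4_total": pick({"S4c": 1, "S4n": 1, "pS2_S4_c": 1,
                             "pS2_S4_n": 1}),
        "T1R_total": pick({"T1R": 1, "LRC_surf": 1, "LRC_EE": 1,
                           "LRC_cave": 1, "S7LRC_EE": 1, "S7LRC_cave": 1}),
        "T2R_total": pick({"T2R": 1, "TGFB_T2R": 1, "LRC_surf": 1,
                           "LRC_EE": 1, "LRC_cave": 1, "S7LRC_EE": 1,
                           "S7LRC_cave": 1}),
    }
    ppm1a = pick({"PPM1A_c": 1, "PPM1A_n": 1, "PPM1A_pS2_n": 1,
                  "PTEN_PPM1A_c": 1, "PTEN_PPM1A_n": 1,
                  "PTEN_PPM1A_pS2_n": 1, "pS2_PTEN_PPM1A_c": 1})
    if ppm1a:
        out["PPM1A_total"] = ppm1a
    pten = pick({"PTEN_c": 1, "PTEN_n": 1, "pS2_PTEN_c": 1,
                 "pS2_PTEN_PPM1A_c": 1, "PTEN_PPM1A_c": 1,
                 "PTEN_PPM1A_n": 1, "PTEN_PPM1A_pS2_n": 1})
    if pten:
        out["PTEN_total"] = pten
        out["PTEN_PPM1A_complex"] = pick({"PTEN_PPM1A_c": 1,
                                          "PTEN_PPM1A_n": 1})
    return out


def conserved_moieties(network: ReactionNetwork) -> dict[str, dict[str, float]]:
    """Moiety definitions used for conservation checks."""
    w = observable_weights(network)
    moieties = {"Smad2": w["Smad2_total"], "Smad4": w["Smad4_total"],
                "T1R": w["T1R_total"], "T2R": w["T2R_total"]}
    if "PPM1A_total" in w:
        moieties["PPM1A"] = w["PPM1A_total"]
    if "PTEN_total" in w:
        moieties["PTEN"] = w["PTEN_total"]
    return moieties


# -- model variant ---------------------------------------------------------

#: Effect -> free (estimated) rate-constant names.
EFFECT_PARAMETERS: dict[str, tuple[str, ...]] = {
    DEPHOSPHORYLATION: ("kdephos",),
    RECEPTOR_DEGRADATION: ("klid",),
    PSMAD_DEGRADATION: ("kdeg_pSmad2",),
    ENDOGENOUS_SMAD_TURNOVER: ("kdeg_S2",),
    PPM1A_STABILIZATION: ("kon_pten", "kimp_pp"),
    PPM1A_EXPRESSION: ("kinduce_PPM1A",),
    ISMAD_FEEDBACK: ("kprod_S7", "ka_S7_LRC"),
}

DEFAULT_BOUNDS = (1e-8, 1e3)


@dataclass
class ModelVariant:
    """One assembled member of the model family."""

    model_id: str
    effects: frozenset[str]
    network: ReactionNetwork
    estimated_parameters: list[str]
    fixed_parameters: list[str]
    derived_parameters: dict[str, Callable[[Mapping[str, float]], float]] = \
        field(default_factory=dict)
    equilibrated_state: np.ndarray | None = None

    @property
    def has_explicit_ppm1a(self) -> bool:
        return bool(self.effects & {PPM1A_STABILIZATION, PPM1A_EXPRESSION})

    def with_parameters(self, overrides: Mapping[str, float]) -> "ModelVariant":
        """Copy with updated rate constants (derived ties re-applied).

        The cached equilibrated state is dropped: callers re-equilibrate.
        """
        params = dict(overrides)
        merged = self.network.parameters.updated(params)
        for name, rule in self.derived_parameters.items():
            if name not in params:
                merged[name] = rule(merged)
        return ModelVariant(
            model_id=self.model_id,
            effects=self.effects,
            network=self.network.with_parameters(merged),
            estimated_parameters=list(self.estimated_parameters),
            fixed_parameters=list(self.fixed_parameters),
            derived_parameters=dict(self.derived_parameters),
            equilibrated_state=None,
        )


def assemble_model(model_id: str | int,
                   parameters: Mapping[str, float] | None = None) -> ModelVariant:
    """Build a model variant from the shared skeleton plus its effect blocks."""
    mid = str(model_id)
    if mid not in MODEL_EFFECTS:
        raise NetworkConfigError(
            f"unknown model id {model_id!r}; choose from {MODEL_IDS}"
        )
    effects = MODEL_EFFECTS[mid]
    explicit_ppm1a = bool(effects & {PPM1A_STABILIZATION, PPM1A_EXPRESSION})
    species, reactions, sources = _skeleton()
    for flag in ALL_EFFECTS:
        if flag in effects:
            if flag == DEPHOSPHORYLATION and explicit_ppm1a:
                # dephosphorylation is realised by the explicit PPM1A
                # two-step catalysis, not the implicit first-order lump
                continue
            sp, rx = _effect_block(flag)
            existing = {s.name for s in species}
            species += [s for s in sp if s.name not in existing]
            existing_rx = {r.name for r in reactions}
            new_rx = [r for r in rx if r.name not in existing_rx]
            reactions += new_rx
            sources.update({r.name: f"effect:{flag}" for r in new_rx})
    if ISMAD_FEEDBACK in effects:
        # Smad7 becomes dynamic in the I-Smad feedback variant
        species = [
            Species(s.name, s.compartment, s.initial_concentration, False)
            if s.name == "SMAD7" else s
            for s in species
        ]

    params = default_parameters()
    if PPM1A_EXPRESSION in effects:
        # expression-driven upregulation needs a slowly turning-over PPM1A
        # pool to act as the slow feedback mode (the stabilisation variants
        # get slowness from degradation protection instead)
        params["kdeg_PPM1A"] = 0.004
        params["ksyn_PPM1A"] = 0.004 * 30.0
    if parameters:
        params = params.updated(parameters)

    free: list[str] = []
    for flag in ALL_EFFECTS:
        if flag in effects:
            if flag == DEPHOSPHORYLATION and explicit_ppm1a:
                free.append("kcat_dephos")
                continue
            free.extend(EFFECT_PARAMETERS[flag])
    fixed = [p for p in params if p not in free]

    derived: dict[str, Callable[[Mapping[str, float]], float]] = {}
    if ENDOGENOUS_SMAD_TURNOVER in effects:
        # flux balance at the unstimulated steady state keeps total Smad2
        # at its measured level whatever the turnover rate
        derived["ksyn_S2"] = lambda p: p["kdeg_S2"] * TOTAL_SMAD2_NM
        params["ksyn_S2"] = derived["ksyn_S2"](params)

    network = ReactionNetwork(
        name=f"Model {mid}", species=species, reactions=reactions,
        parameters=params, reaction_sources=sources,
    )
    findings = network.validate()
    if findings:
        raise NetworkConfigError(
            f"model {mid} failed validation: {findings}"
        )
    return ModelVariant(mid, effects, network, free, fixed, derived)


# -- equilibration ---------------------------------------------------------

def equilibrate(model: ModelVariant, horizon: float = 1e4,
                rtol: float = 1e-10, atol: float = 1e-10) -> np.ndarray:
    """Pre-stimulus steady state: integrate for ``horizon`` minutes with
    zero ligand and return the final state.

    Warns if the relative rate of change at the horizon exceeds 1e-8/min;
    raises on divergence (any species above 1e9 nM).  The result is cached
    on ``model.equilibrated_state``.
    """
    net = model.network
    y0 = net.initial_state()
    y0[net.index["TGFB"]] = 0.0
    rhs = net.build_rhs()
    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"equilibration failed for model "
                           f"{model.model_id}: {sol.message}")
    y = sol.y[:, -1]
    if not np.all(np.isfinite(y)):
        raise RuntimeError(
            f"equilibration of model {model.model_id} produced non-finite "
            f"concentrations; check parameters"
        )
    if np.any(y > 1e9):
        worst = net.species_names[int(np.argmax(y))]
        raise RuntimeError(
            f"model {model.model_id} diverged during equilibration "
            f"({worst} > 1e9 nM); check parameters"
        )
    dy = rhs(horizon, y)
    scale = np.maximum(np.abs(y), 1.0)
    if np.max(np.abs(dy) / scale) > 1e-8:
        warnings.warn(
            f"model {model.model_id}: not fully equilibrated at "
            f"{horizon:g} min (max relative rate "
            f"{np.max(np.abs(dy) / scale):.2e}/min)",
            RuntimeWarning,
        )
    y = np.clip(y, 0.0, None)
    model.equilibrated_state = y
    return y


def estimated_parameter_schema(model_id: str | int) -> list[tuple[str, tuple[float, float], str]]:
    """Free-parameter list for the fitter: (name, bounds, scale)."""
    model = assemble_model(model_id)
    return [(name, DEFAULT_BOUNDS, "log10")
            for name in model.estimated_parameters]
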