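"""Model-family assembly, the effect matrix, and pre-stimulus steady
states."""

import numpy as np
import pytest

from tgfsmad import (
    NetworkConfigError,
    assemble_model,
    equilibrate,
    estimated_parameter_schema,
)
from tgfsmad.models import (
    DEPHOSPHORYLATION,
    ENDOGENOUS_SMAD_TURNOVER,
    ISMAD_FEEDBACK,
    MODEL_EFFECTS,
    PPM1A_EXPRESSION,
    PPM1A_STABILIZATION,
    PSMAD_DEGRADATION,
    RECEPTOR_DEGRADATION,
)

# hard-coded copy of the model x effect matrix, asserted against the
# registry to catch accidental edits
EFFECT_MATRIX = {
    #      dephos  recdeg  psdeg  turnover  stabil
    "1": ("+", "-", "-", "-", "-"),
    "2": ("+", "+", "-", "-", "-"),
    "3": ("-", "+", "-", "-", "-"),
    "4": ("-", "-", "+", "-", "-"),
    "5": ("+", "+", "+", "-", "-"),
    "6": ("+", "-", "+", "-", "-"),
    "7": ("+", "-", "+", "+", "-"),
    "8": ("+", "-", "+", "+", "+"),
}
EFFECT_ORDER = (DEPHOSPHORYLATION, RECEPTOR_DEGRADATION, PSMAD_DEGRADATION,
                ENDOGENOUS_SMAD_TURNOVER, PPM1A_STABILIZATION)


def test_effect_matrix_fidelity():
    for mid, row in EFFECT_MATRIX.items():
        expected = frozenset(effect for effect, sign
                             in zip(EFFECT_ORDER, row) if sign == "+")
        assert MODEL_EFFECTS[mid] == expected, f"Model {mid}"


def test_supplementary_variants():
    assert MODEL_EFFECTS["S1"] == MODEL_EFFECTS["5"] | {ISMAD_FEEDBACK}
    assert PPM1A_EXPRESSION in MODEL_EFFECTS["S2"]
    assert PPM1A_STABILIZATION not in MODEL_EFFECTS["S2"]
    assert MODEL_EFFECTS["S3"] == frozenset({DEPHOSPHORYLATION,
                                             PPM1A_STABILIZATION})


class TestAssembly:
    def test_model1_single_negative_regulation_reaction(self):
        m = assemble_model(1)
        effect_rxns = [r for r, src in m.network.reaction_sources.items()
                       if src.startswith("effect:")]
        assert effect_rxns == ["dephos_pS2n"]

    def test_model5_reaction_complement(self, model5):
        names = {r.name for r in model5.network.reactions}
        assert {"lid_LRC_cave", "dephos_pS2n", "smurf_deg_pS2n"} <= names
        assert "syn_S2" not in names  # no Smad turnover in Model 5

    def test_model8_replaces_implicit_dephosphorylation(self, model8):
        names = {r.name for r in model8.network.reactions}
        assert "dephos_pS2n" not in names
        assert {"cat_bind", "cat_dephos", "ternary_release",
                "import_PTEN_PPM1A"} <= names

    def test_unknown_model_id(self):
        with pytest.raises(NetworkConfigError, match="unknown model id"):
            assemble_model("9")

    def test_smad7_becomes_dynamic_in_s1(self):
        s1 = assemble_model("S1")
        assert not s1.network.species_by_name("SMAD7").constant
        m5 = assemble_model("5")
        assert m5.network.species_by_name("SMAD7").constant


class TestParameterSchema:
    def test_model3_has_receptor_rate_only(self):
        names = [n for n, _, _ in estimated_parameter_schema(3)]
        assert "klid" in names and "kdephos" not in names

    def test_model4_has_degradation_rate_only(self):
        names = [n for n, _, _ in estimated_parameter_schema(4)]
        assert "kdeg_pSmad2" in names and "klid" not in names

    def test_model1_has_dephosphorylation_rate(self):
        names = [n for n, _, _ in estimated_parameter_schema(1)]
        assert names == ["kdephos"]

    def test_bounds_and_scale(self):
        for name, bounds, scale in estimated_parameter_schema(8):
            assert bounds == (1e-8, 1e3) and scale == "log10"


class TestEquilibrate:
    def test_no_phospho_smad_without_ligand(self, model1):
        idx = model1.network.index
        y = model1.equilibrated_state
        for name in ("pS2c", "pS2n", "pS2_S4_n", "pS2_pS2_n"):
            assert y[idx[name]] == pytest.approx(0.0, abs=1e-8)

    def test_monomer_ratio_matches_shuttling_rates(self, model1):
        """Oracle: for a two-compartment shuttle at steady state the
        relative nuclear/cytoplasmic ratio equals import/export."""
        p = model1.network.parameters
        y = model1.equilibrated_state
        idx = model1.network.index
        ratio = y[idx["S2n"]] / y[idx["S2c"]]
        assert ratio == pytest.approx(p["kin_S2"] / p["kex_S2"], rel=1e-6)
        ratio4 = y[idx["S4n"]] / y[idx["S4c"]]
        assert ratio4 == pytest.approx(p["kin_S4"] / p["kex_S4"], rel=1e-6)

    def test_ppm1a_rest_level_is_synthesis_degradation_balance(self, model8):
        """Closed form: total PPM1A at rest = ksyn/kdeg (no phospho-Smad,
        so the PTEN branch is inactive)."""
        p = model8.network.parameters
        idx = model8.network.index
        y = model8.equilibrated_state
        total = y[idx["PPM1A_c"]] + y[idx["PPM1A_n"]]
        assert total == pytest.approx(p["ksyn_PPM1A"] / p["kdeg_PPM1A"],
                                      rel=1e-6)
        assert y[idx["PTEN_PPM1A_c"]] == pytest.approx(0.0, abs=1e-8)

    def test_steady_state_persists(self, model1):
        """Simulating a further week without ligand moves nothing by more
        than 0.1 %."""
        from scipy.integrate import solve_ivp
        y0 = model1.equilibrated_state
        sol = solve_ivp(model1.network.build_rhs(), (0.0, 1e4), y0,
                        method="LSODA", rtol=1e-10, atol=1e-10)
        y1 = sol.y[:, -1]
        scale = np.maximum(np.abs(y0), 1e-6)
        assert np.max(np.abs(y1 - y0) / scale) < 1e-3

    def test_shared_species_share_steady_state(self):
        """Models 1-7 agree on all shared pre-stimulus concentrations;
        Model 8's PPM1A additions leave the shared species unchanged."""
        states = {}
        for mid in ["1", "2", "3", "4", "5", "6", "7", "8"]:
            m = assemble_model(mid)
            equilibrate(m)
            states[mid] = {n: m.equilibrated_state[m.network.index[n]]
                           for n in m.network.species_names}
        ref = states["1"]
        for mid, st in states.items():
            for name, value in ref.items():
                if name in st:
                    assert st[name] == pytest.approx(value, rel=0.01,
                                                     abs=1e-6), \
                        f"Model {mid} species {name}"
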