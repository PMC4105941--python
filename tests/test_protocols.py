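"""Stimulation protocols, perturbations and observables."""

import numpy as np
import pytest

from tgfsmad import (
    CYCLOHEXIMIDE,
    LONG_EXPOSURE,
    MG132,
    SHORT_EXPOSURE,
    StimulusProtocol,
    apply_perturbation,
    assemble_model,
    dose_convert,
    equilibrate,
    simulate,
)
from tgfsmad.models import TOTAL_SMAD2_NM


class TestDoseConvert:
    def test_standard_dose_is_80_pM(self):
        assert dose_convert(2.0) == pytest.approx(80.0)

    def test_zero_dose(self):
        assert dose_convert(0.0) == 0.0

    def test_linearity(self):
        assert dose_convert(1.0) == pytest.approx(40.0)
        assert dose_convert(0.5) == pytest.approx(0.25 * dose_convert(2.0))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            dose_convert(2.0, molecular_mass_kDa=0.0)


class TestSimulate:
    def test_zero_dose_stays_at_steady_state(self, model1):
        traj = simulate(model1, StimulusProtocol(0.0, "long",
                                                 horizon=1440.0),
                        np.linspace(0, 1440, 25))
        ps = traj.observe("PSmad2_total")
        assert np.max(ps) < 1e-6
        t1r = traj.observe("T1R_total")
        assert np.ptp(t1r) / t1r[0] < 1e-6

    def test_model1_plateaus_after_peak(self, model1):
        traj = simulate(model1, LONG_EXPOSURE)
        ps = traj.observe("PSmad2_total")
        t = traj.times
        peak = ps.max()
        at_1h = ps[t == 60][0]
        assert abs(at_1h - ps[-1]) < 0.10 * peak  # no extended decline

    def test_model5_with_zeroed_effects_reproduces_model1(self, model1,
                                                          model5):
        """Effect-nesting oracle: zeroing the receptor- and P-Smad-
        degradation rates reduces Model 5 to Model 1 exactly."""
        reduced = model5.with_parameters({"klid": 0.0, "kdeg_pSmad2": 0.0})
        equilibrate(reduced)
        t = np.linspace(0, 1440, 49)
        a = simulate(model1, LONG_EXPOSURE, t).observe("PSmad2_total")
        b = simulate(reduced, LONG_EXPOSURE, t).observe("PSmad2_total")
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8)

    def test_total_smad2_constant_in_model1(self, model1):
        traj = simulate(model1, LONG_EXPOSURE, np.linspace(0, 1440, 97))
        total = traj.observe("Smad2_total")
        np.testing.assert_allclose(total, TOTAL_SMAD2_NM, rtol=1e-6)

    def test_t1r_flat_in_model8(self, model8):
        traj = simulate(model8, LONG_EXPOSURE, np.linspace(0, 1440, 49))
        t1r = traj.observe("T1R_total")
        assert np.ptp(t1r) / t1r[0] < 0.10

    def test_no_negative_concentrations(self, model8):
        traj = simulate(model8, SHORT_EXPOSURE)
        assert traj.states.min() >= -1e-8

    @pytest.mark.parametrize("mid", ["1", "2", "8"])
    def test_washout_eliminates_phospho_smad_within_4h(self, mid):
        m = assemble_model(mid)
        equilibrate(m)
        traj = simulate(m, SHORT_EXPOSURE)
        ps = traj.observe("PSmad2_total")
        t = traj.times
        assert ps[t == 240][0] < 0.05 * ps.max()

    def test_normalized_observable_peaks_at_one(self, model1):
        traj = simulate(model1, LONG_EXPOSURE)
        assert traj.observe("PSmad2_total", normalize="max").max() == \
            pytest.approx(1.0)

    def test_dose_monotonicity_at_45min(self, model8):
        doses = (0.025, 0.125, 0.5, 2.0)
        readouts = []
        for dose in doses:
            traj = simulate(model8, StimulusProtocol(dose, "long",
                                                     horizon=60.0),
                            np.array([0.0, 45.0]))
            readouts.append(traj.observe("PSmad2_total")[-1])
        assert np.all(np.diff(readouts) >= -1e-9)


class TestPerturbations:
    def test_mg132_changes_only_the_smurf_rate(self, model8):
        treated = apply_perturbation(model8, MG132)
        diff = {k: (model8.network.parameters[k],
                    treated.network.parameters[k])
                for k in model8.network.parameters
                if model8.network.parameters[k] !=
                treated.network.parameters[k]}
        assert set(diff) == {"kdeg_pSmad2"}
        assert treated.network.parameters["kdeg_pSmad2"] == 0.0
        assert treated.network.parameters["kdeg_PPM1A"] == \
            model8.network.parameters["kdeg_PPM1A"]

    def test_mg132_noop_warns_on_model_without_target(self, model1):
        with pytest.warns(RuntimeWarning, match="no-op"):
            treated = apply_perturbation(model1, MG132)
        assert dict(treated.network.parameters) == \
            dict(model1.network.parameters)

    def test_cycloheximide_halves_every_synthesis_rate(self, model8):
        treated = apply_perturbation(model8, CYCLOHEXIMIDE)
        for rxn in model8.network.reactions:
            k = rxn.rate_constant
            if not rxn.reactants:
                assert treated.network.parameters[k] == \
                    pytest.approx(0.5 * model8.network.parameters[k])
            elif k not in {r.rate_constant for r in
                           model8.network.reactions if not r.reactants}:
                assert treated.network.parameters[k] == \
                    model8.network.parameters[k]

    def test_original_model_untouched(self, model8):
        before = dict(model8.network.parameters)
        apply_perturbation(model8, MG132)
        assert dict(model8.network.parameters) == before


class TestTrajectory:
    def test_tidy_frame_schema(self, model1):
        traj = simulate(model1, LONG_EXPOSURE, np.linspace(0, 1440, 5))
        frame = traj.to_frame()
        assert set(frame.columns) == {"time_min", "name", "value", "kind"}
        assert set(frame["kind"]) == {"species", "observable"}

    def test_unknown_observable_raises(self, model1):
        traj = simulate(model1, LONG_EXPOSURE, np.linspace(0, 1440, 5))
        with pytest.raises(KeyError, match="PPM1A_total"):
            traj.observe("PPM1A_total")
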