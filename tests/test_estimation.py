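"""Objective, multistart fitting, constraints and misfit detection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tgfsmad import (
    NoiseModel,
    SmadSignalingModel,
    assemble_model,
    constrained_fit_model7,
    fit_multistart,
    generate_bundle,
    sse_objective,
)
from tgfsmad.estimation import (
    FIT_CHANNELS,
    TimeSeriesDataset,
    _systematic_misfit,
    standard_channels,
)


class TestSseObjective:
    def test_zero_at_truth_on_noise_free_data(self, clean_bundle, model8):
        sse = sse_objective(model8,
                            clean_bundle.dataset.subset(FIT_CHANNELS))
        assert sse == pytest.approx(0.0, abs=1e-8)

    def test_single_record_squared_residual(self, model1):
        spec = standard_channels()["pSmad2_long"]
        # a lone record at t=0 where the normalised observable is 0
        data = pd.DataFrame({"channel_id": ["pSmad2_long"], "time": [0.0],
                             "replicate": [0], "value": [2.0]})
        ds = TimeSeriesDataset(data, {"pSmad2_long": spec})
        assert sse_objective(model1, ds) == pytest.approx(4.0, abs=1e-8)

    def test_invariant_to_record_order(self, clean_bundle, model1):
        ds = clean_bundle.dataset.subset(FIT_CHANNELS)
        shuffled = TimeSeriesDataset(
            ds.data.sample(frac=1.0, random_state=3).reset_index(drop=True),
            ds.channels)
        assert sse_objective(model1, ds) == \
            pytest.approx(sse_objective(model1, shuffled), rel=1e-12)


class TestFitMultistart:
    def test_deterministic_given_seed(self, noisy_bundle):
        ds = noisy_bundle.dataset.subset(FIT_CHANNELS)
        fits = [fit_multistart(assemble_model("1"), ds, n_starts=2, seed=5)
                for _ in range(2)]
        assert fits[0].params == fits[1].params
        assert fits[0].sse == fits[1].sse

    def test_start_at_truth_recovers_noise_floor(self):
        # a bundle generated by the fitted model at its default rates puts
        # the first start at the optimum; a single start must stay there
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = generate_bundle("6", noise=NoiseModel(cv=0.0), seed=4)
        m = assemble_model("6")
        fit = fit_multistart(m, bundle.dataset.subset(FIT_CHANNELS),
                             n_starts=1, seed=0)
        assert fit.sse < 1e-6
        for name in fit.params:
            assert fit.params[name] == pytest.approx(
                m.network.parameters[name], rel=1e-3)

    def test_winner_is_minimum_over_starts(self, noisy_bundle):
        fit = fit_multistart(assemble_model("1"),
                             noisy_bundle.dataset.subset(FIT_CHANNELS),
                             n_starts=3, seed=2)
        assert fit.sse == pytest.approx(fit.starts["sse"].min())

    def test_requires_free_parameters(self, noisy_bundle):
        m = assemble_model("1")
        with pytest.raises(ValueError):
            fit_multistart(m, noisy_bundle.dataset.subset(FIT_CHANNELS),
                           parameter_names=[])


class TestParameterRecovery:
    def test_noise_free_recovery_from_displaced_truth(self):
        """Identifiable rates are recovered to well under 1 % from
        noise-free data generated away from the fitter's defaults."""
        truth = {"kdephos": 0.25, "kdeg_pSmad2": 0.012}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = generate_bundle("6", truth_params=truth,
                                     noise=NoiseModel(cv=0.0), seed=3)
            fit = fit_multistart(assemble_model("6"),
                                 bundle.dataset.subset(FIT_CHANNELS),
                                 n_starts=2, seed=3)
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=0.01)


class TestConstrainedModel7:
    def test_constraint_reported_and_satisfied(self, noisy_bundle):
        m7 = assemble_model("7")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = constrained_fit_model7(
                m7, noisy_bundle.dataset.subset(FIT_CHANNELS),
                n_starts=2, seed=1)
        dev = fit.diagnostics["max_total_smad2_deviation"]
        assert dev <= 0.05
        assert fit.diagnostics["constraint_satisfied"]

    def test_synthesis_balances_degradation_at_rest(self):
        """Flux-balance oracle: with the synthesis tie, production equals
        the basal degradation flux at the unstimulated steady state."""
        from tgfsmad.models import TOTAL_SMAD2_NM, equilibrate
        m7 = assemble_model("7", {"kdeg_S2": 0.002})
        p = m7.network.parameters
        assert p["ksyn_S2"] == pytest.approx(0.002 * TOTAL_SMAD2_NM)
        equilibrate(m7)
        y = m7.equilibrated_state
        idx = m7.network.index
        deg_flux = p["kdeg_S2"] * (y[idx["S2c"]] + y[idx["S2n"]]
                                   + y[idx["pS2c"]] + y[idx["pS2n"]])
        assert deg_flux == pytest.approx(p["ksyn_S2"], rel=1e-6)

    def test_requires_turnover_variant(self, noisy_bundle):
        with pytest.raises(ValueError):
            constrained_fit_model7(
                assemble_model("1"),
                noisy_bundle.dataset.subset(FIT_CHANNELS))


class TestSystematicMisfit:
    def test_one_sided_large_residuals_flagged(self):
        res = np.array([0.0, -0.1, 0.05, -0.5, -0.6, -0.7, -0.55, -0.4])
        sem = np.full(res.size, 0.05)
        assert _systematic_misfit(res, sem)

    def test_noise_scale_residuals_pass(self, rng):
        res = rng.normal(0.0, 0.05, 10)
        sem = np.full(10, 0.06)
        assert not _systematic_misfit(res, sem)

    def test_short_series_never_flagged(self):
        assert not _systematic_misfit(np.array([1.0, -1.0, 1.0]),
                                      np.array([0.01] * 3))


class TestModelResultsInterface:
    def test_fit_returns_results_with_summary(self, noisy_bundle):
        model = SmadSignalingModel(noisy_bundle.dataset, model_id="1")
        res = model.fit(n_starts=2, seed=0)
        text = res.summary()
        assert "Model 1" in text and "kdephos" in text
        assert res.params.index.tolist() == ["kdephos"]
        assert res.sse >= 0

    def test_predict_matches_channel_grid(self, noisy_bundle):
        model = SmadSignalingModel(noisy_bundle.dataset, model_id="1")
        res = model.fit(n_starts=1, seed=0)
        pred = res.predict("pSmad2_long")
        spec = noisy_bundle.dataset.channels["pSmad2_long"]
        assert pred.index.tolist() == list(spec.times)
        assert pred.max() == pytest.approx(1.0)

    def test_from_dataframe_roundtrip(self, noisy_bundle):
        frame = noisy_bundle.dataset.data
        model = SmadSignalingModel.from_dataframe(frame, model_id="6")
        assert set(model.data.channels) == set(noisy_bundle.dataset.channels)
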