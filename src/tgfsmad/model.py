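"""Top-level modelling interface: a Model object built from data whose
``fit()`` returns a Results object.

This wraps the model family, protocols and multistart estimator in the
style of statistical modelling packages::

    data = tgfsmad.generate_bundle(seed=0).dataset
    model = tgfsmad.SmadSignalingModel(data, model_id="6")
    res = model.fit(n_starts=5, seed=0)
    print(res.summary())
    traj = res.simulate()            # 24-hr continuous 2 ng/ml TGF-beta
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimation import (
    FIT_CHANNELS,
    FIT_CHANNELS_PPM1A,
    FitResult,
    TimeSeriesDataset,
    constrained_fit_model7,
    fit_multistart,
    sse_objective,
    standard_channels,
)
from .models import ModelVariant, assemble_model, equilibrate
from .protocols import LONG_EXPOSURE, StimulusProtocol, Trajectory, simulate


class SmadSignalingModel:
    """A TGF-beta/Smad pathway variant bound to a time-course dataset.

    Parameters
    ----------
    data : TimeSeriesDataset
        Tidy time-course bundle (see :func:`tgfsmad.generate_bundle` or
        :meth:`from_dataframe`).
    model_id : str
        Variant identifier ("1".."8", "S1", "S2", "S3").
    fit_channels : sequence of str, optional
        Channel ids used in the objective; defaults to the phospho-Smad2
        short+long channels, plus PPM1A for variants with an explicit
        PPM1A pool.
    parameters : mapping, optional
        Rate-constant overrides applied to the variant's defaults.
    """

    def __init__(self, data: TimeSeriesDataset, model_id: str | int = "8",
                 fit_channels: Sequence[str] | None = None,
                 parameters: Mapping[str, float] | None = None):
        self.data = data
        self.variant: ModelVariant = assemble_model(model_id, parameters)
        if fit_channels is None:
            fit_channels = (FIT_CHANNELS_PPM1A
                            if self.variant.has_explicit_ppm1a
                            else FIT_CHANNELS)
        self.fit_channels = [c for c in fit_channels if c in data.channels]
        self.model_id = str(model_id)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, model_id: str | int = "8",
                       **kwargs) -> "SmadSignalingModel":
        """Build from a tidy frame with columns
        (channel_id, time, replicate, value) on the standard channels."""
        channels = standard_channels()
        present = {c: channels[c] for c in set(frame["channel_id"])
                   if c in channels}
        return cls(TimeSeriesDataset(frame.reset_index(drop=True), present),
                   model_id, **kwargs)

    @property
    def exog_names(self) -> list[str]:
        """Names of the free (estimated) rate constants."""
        return list(self.variant.estimated_parameters)

    def loglike_sse(self, params: Mapping[str, float] | None = None) -> float:
        """Sum of squared errors at the given (or current) parameters."""
        return sse_objective(self.variant,
                             self.data.subset(self.fit_channels), params)

    def fit(self, n_starts: int = 5, seed: int | None = 0,
            constrain_total_smad: bool | None = None,
            **kwargs) -> "SmadSignalingResults":
        """Multistart bounded least squares on the fit channels.

        ``constrain_total_smad`` forces the total-Smad2 constancy
        constraint (defaults to on for Model 7, mirroring how the
        turnover-balanced variant is fitted).
        """
        data = self.data.subset(self.fit_channels)
        if constrain_total_smad is None:
            constrain_total_smad = self.model_id == "7"
        if constrain_total_smad:
            raw = constrained_fit_model7(self.variant, data,
                                         n_starts=n_starts, seed=seed,
                                         **kwargs)
        else:
            raw = fit_multistart(self.variant, data, n_starts=n_starts,
                                 seed=seed, **kwargs)
        return SmadSignalingResults(self, raw)


class SmadSignalingResults:
    """Estimates, fit diagnostics and simulation access for a fitted
    pathway variant."""

    def __init__(self, model: SmadSignalingModel, raw: FitResult):
        self.model = model
        self.raw = raw
        self.fitted_variant = model.variant.with_parameters(raw.params)
        equilibrate(self.fitted_variant)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.raw.params, name="estimate")

    @property
    def sse(self) -> float:
        return self.raw.sse

    @property
    def sse_by_channel(self) -> dict[str, float]:
        return dict(self.raw.sse_by_channel)

    def summary(self) -> str:
        return self.raw.summary()

    def simulate(self, protocol: StimulusProtocol = LONG_EXPOSURE,
                 times: np.ndarray | None = None) -> Trajectory:
        """Simulate the fitted variant under a stimulation protocol."""
        return simulate(self.fitted_variant, protocol, times)

    def predict(self, channel_id: str) -> pd.Series:
        """Normalised model curve on one channel's observation grid."""
        spec = self.model.data.channels[channel_id]
        traj = simulate(self.fitted_variant, spec.protocol,
                        np.asarray(spec.times))
        values = spec.normalize(traj.observe(spec.observable))
        return pd.Series(values, index=list(spec.times), name=channel_id)

    def plot_fit(self, channel_id: str, ax=None):
        """Data (replicate points) and fitted curve for one channel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.model.data.data
        sub = sub[sub["channel_id"] == channel_id]
        ax.plot(sub["time"], sub["value"], "o", alpha=0.6, label="data")
        pred = self.predict(channel_id)
        ax.plot(pred.index, pred.values, "-", label=f"Model "
                f"{self.model.model_id}")
        ax.set_xlabel("time (min)")
        ax.set_ylabel(channel_id)
        ax.legend()
        return ax
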