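"""Multistart least-squares estimation and the model-rejection workflow.

Models are fitted to phospho-Smad2 time courses from the short- and
long-exposure protocols simultaneously (plus the PPM1A channel for models
with an explicit PPM1A pool), with the sum of squared errors as the
objective.  The receptor and total-Smad channels are treated as model
predictions and enter the rejection verdict, mirroring how the measured
type-I receptor and total R-Smad time courses discriminate between
candidate negative-regulation mechanisms.

Optimisation runs in log10-parameter space with box bounds and randomly
scattered multistart initial guesses; the contract is the multistart-best
SSE, not the identity of the local optimiser.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    DEFAULT_BOUNDS,
    ModelVariant,
    TOTAL_SMAD2_NM,
    assemble_model,
    equilibrate,
)
from .protocols import StimulusProtocol, simulate

logger = logging.getLogger(__name__)

FAILURE_PENALTY = 1e12  # SSE assigned when integration fails inside a fit

#: observation grids (minutes)
SHORT_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0)
LONG_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 120.0, 240.0, 360.0, 480.0,
             720.0, 1440.0)
T1R_GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0, 360.0, 480.0, 720.0, 1440.0)
TSMAD_GRID = (0.0, 60.0, 120.0, 240.0, 480.0, 720.0, 1440.0)
PPM1A_GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0)


@dataclass(frozen=True)
class ChannelSpec:
    """One measured channel: protocol, observable, grid and normalisation."""

    channel_id: str
    protocol: StimulusProtocol
    observable: str
    times: tuple[float, ...]
    normalization: str = "relative_to_max"  # | relative_to_t0 | absolute_nM

    def normalize(self, values: np.ndarray) -> np.ndarray:
        if self.normalization == "relative_to_max":
            peak = float(np.max(values))
            return values / peak if peak > 0 else values
        if self.normalization == "relative_to_t0":
            base = float(values[0])
            return values / base if base > 0 else values
        if self.normalization == "absolute_nM":
            return values
        raise ValueError(f"unknown normalization {self.normalization!r}")


def standard_channels(horizon: float = 1440.0) -> dict[str, ChannelSpec]:
    """The default experimental bundle layout.

    Western-blot-style channels are fitted as relative-to-max (P-Smad2) or
    fold-over-baseline (T1R, PPM1A, total Smad2) since absolute units are
    unavailable for densitometry data.
    """
    long_p = StimulusProtocol(2.0, "long", horizon=horizon)
    short_p = StimulusProtocol(2.0, "short", t_wash=30.0, horizon=horizon)
    return {
        "pSmad2_short": ChannelSpec("pSmad2_short", short_p, "PSmad2_total",
                                    SHORT_GRID, "relative_to_max"),
        "pSmad2_long": ChannelSpec("pSmad2_long", long_p, "PSmad2_total",
                                   LONG_GRID, "relative_to_max"),
        "T1R": ChannelSpec("T1R", long_p, "T1R_total", T1R_GRID,
                           "relative_to_t0"),
        "Smad2_total": ChannelSpec("Smad2_total", long_p, "Smad2_total",
                                   TSMAD_GRID, "relative_to_t0"),
        "PPM1A": ChannelSpec("PPM1A", long_p, "PPM1A_total", PPM1A_GRID,
                             "relative_to_t0"),
    }


#: channels a model is fitted to (the rest are predictions)
FIT_CHANNELS = ("pSmad2_short", "pSmad2_long")
FIT_CHANNELS_PPM1A = ("pSmad2_short", "pSmad2_long", "PPM1A")

#: short labels used in the rejection verdict row
VERDICT_LABELS = {"pSmad2_short": "pS", "pSmad2_long": "pS", "T1R": "T1R",
                  "Smad2_total": "tS", "PPM1A": "PPM1A"}


@dataclass
class TimeSeriesDataset:
    """Tidy records of (channel_id, time, replicate, value).

    ``channels`` maps channel ids to their :class:`ChannelSpec`; values are
    already on each channel's normalised scale.
    """

    data: pd.DataFrame
    channels: dict[str, ChannelSpec]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        required = {"channel_id", "time", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.data["time"] < 0).any():
            raise ValueError("negative observation times")
        unknown = set(self.data["channel_id"]) - set(self.channels)
        if unknown:
            raise ValueError(f"records reference unknown channels {unknown}")

    def subset(self, channel_ids: Iterable[str]) -> "TimeSeriesDataset":
        keep = [c for c in channel_ids if c in set(self.data["channel_id"])]
        return TimeSeriesDataset(
            self.data[self.data["channel_id"].isin(keep)].reset_index(drop=True),
            {c: self.channels[c] for c in keep},
            self.weights,
        )

    def channel_ids(self) -> list[str]:
        return sorted(set(self.data["channel_id"]))

    def mean_curve(self, channel_id: str) -> pd.Series:
        """Replicate-mean value per time point (index: time)."""
        sub = self.data[self.data["channel_id"] == channel_id]
        return sub.groupby("time")["value"].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# -- objective -------------------------------------------------------------

def _simulate_channels(model: ModelVariant, channels: Sequence[ChannelSpec],
                       rtol: float, atol: float) -> dict[str, np.ndarray]:
    """One simulation per distinct protocol; normalised channel curves."""
    if model.equilibrated_state is None:
        equilibrate(model)
    by_protocol: dict[StimulusProtocol, list[ChannelSpec]] = {}
    for ch in channels:
        by_protocol.setdefault(ch.protocol, []).append(ch)
    out: dict[str, np.ndarray] = {}
    for protocol, chans in by_protocol.items():
        times = np.unique(np.concatenate([np.asarray(c.times) for c in chans]))
        traj = simulate(model, protocol, times, rtol=rtol, atol=atol)
        for ch in chans:
            idx = np.searchsorted(traj.times, np.asarray(ch.times))
            out[ch.channel_id] = ch.normalize(traj.observe(ch.observable)[idx])
    return out


def channel_residuals(model: ModelVariant, dataset: TimeSeriesDataset,
                      params: Mapping[str, float] | None = None,
                      rtol: float = 1e-6, atol: float = 1e-9,
                      ) -> dict[str, np.ndarray]:
    """Per-channel residual vectors (observed minus simulated)."""
    work = model.with_parameters(dict(params)) if params else model
    if params:
        equilibrate(work)
    chans = [dataset.channels[c] for c in dataset.channel_ids()]
    sims = _simulate_channels(work, chans, rtol, atol)
    residuals: dict[str, np.ndarray] = {}
    for ch in chans:
        sub = dataset.data[dataset.data["channel_id"] == ch.channel_id]
        sim_at = dict(zip(ch.times, sims[ch.channel_id]))
        res = sub["value"].to_numpy() - np.array(
            [sim_at[t] for t in sub["time"]])
        if dataset.weights and ch.channel_id in dataset.weights:
            res = res * np.sqrt(dataset.weights[ch.channel_id])
        residuals[ch.channel_id] = res
    return residuals


def sse_objective(model: ModelVariant, dataset: TimeSeriesDataset,
                  params: Mapping[str, float] | None = None,
                  rtol: float = 1e-6, atol: float = 1e-9) -> float:
    """Sum of squared errors of the model against a dataset bundle.

    Simulation failures return a large finite penalty instead of raising,
    which keeps multistart optimisers alive in pathological corners.
    """
    try:
        residuals = channel_residuals(model, dataset, params, rtol, atol)
    except RuntimeError as err:
        logger.warning("integration failure in objective: %s", err)
        return FAILURE_PENALTY
    return float(sum(np.sum(r ** 2) for r in residuals.values()))


# -- multistart fitting ----------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a multistart fit."""

    model_id: str
    parameter_names: list[str]
    params: dict[str, float]
    log10_params: dict[str, float]
    sse: float
    sse_by_channel: dict[str, float]
    winner_start: int
    starts: pd.DataFrame            # start index, SSE, convergence flag
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Model {self.model_id} multistart least-squares fit",
            f"  SSE (best of {len(self.starts)} starts): {self.sse:.6g}",
            f"  winner start: {self.winner_start}   seed: {self.seed}",
            "  parameter        estimate        log10",
        ]
        for name in self.parameter_names:
            lines.append(f"  {name:<16} {self.params[name]:<15.6g} "
                         f"{self.log10_params[name]: .3f}")
        for ch, sse in sorted(self.sse_by_channel.items()):
            lines.append(f"  SSE[{ch}]: {sse:.6g}")
        for key, val in self.diagnostics.items():
            lines.append(f"  {key}: {val}")
        return "\n".join(lines)


def _make_residual_fn(model: ModelVariant, dataset: TimeSeriesDataset,
                      names: Sequence[str], rtol: float, atol: float,
                      n_res: int, extra_residual_fn=None):
    def fn(x: np.ndarray) -> np.ndarray:
        overrides = {n: 10.0 ** v for n, v in zip(names, x)}
        try:
            res = channel_residuals(model, dataset, overrides, rtol, atol)
            parts = [res[c] for c in sorted(res)]
            if extra_residual_fn is not None:
                parts.append(np.atleast_1d(
                    extra_residual_fn(model.with_parameters(overrides))))
            return np.concatenate(parts)
        except (RuntimeError, FloatingPointError) as err:
            logger.warning("integration failure at %s: %s", overrides, err)
            return np.full(n_res, np.sqrt(FAILURE_PENALTY / n_res))

    return fn


def fit_multistart(model: ModelVariant, dataset: TimeSeriesDataset,
                   n_starts: int = 5, seed: int | None = 0,
                   parameter_names: Sequence[str] | None = None,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   rtol: float = 1e-6, atol: float = 1e-9,
                   max_nfev: int | None = None,
                   extra_residual_fn=None) -> FitResult:
    """Bounded multistart least squares in log10-parameter space.

    The first start is the model's current parameter values; the remaining
    ``n_starts - 1`` are log-uniform draws within the bounds.  Deterministic
    given ``seed``.  ``extra_residual_fn(variant) -> array`` may append
    penalty residuals (e.g. a constancy constraint) to the objective.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    names = list(parameter_names if parameter_names is not None
                 else model.estimated_parameters)
    if not names:
        raise ValueError(f"model {model.model_id} has no free parameters")
    lo = np.array([np.log10((bounds or {}).get(n, DEFAULT_BOUNDS)[0])
                   for n in names])
    hi = np.array([np.log10((bounds or {}).get(n, DEFAULT_BOUNDS)[1])
                   for n in names])
    rng = np.random.default_rng(seed)
    x0_default = np.clip(
        np.log10([max(model.network.parameters[n], 10.0 ** lo[i])
                  for i, n in enumerate(names)]), lo, hi)
    # one start at the current values, some local jitters around them
    # (+/- 1.5 decades), the rest global log-uniform draws
    n_local = (n_starts - 1) // 2
    starts = [x0_default]
    starts += [np.clip(x0_default + rng.uniform(-1.5, 1.5, len(names)),
                       lo, hi) for _ in range(n_local)]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - 1 - n_local)]

    n_res = len(dataset.data)
    if extra_residual_fn is not None:
        probe = model.with_parameters(
            {n: 10.0 ** v for n, v in zip(names, x0_default)})
        equilibrate(probe)
        n_res += np.atleast_1d(extra_residual_fn(probe)).size
    fn = _make_residual_fn(model, dataset, names, rtol, atol, n_res,
                           extra_residual_fn)
    rows, solutions = [], []
    for i, x0 in enumerate(starts):
        try:
            # finite-difference step well above the integrator noise
            sol = least_squares(fn, x0, bounds=(lo, hi), method="trf",
                                diff_step=1e-3, xtol=1e-10, ftol=1e-10,
                                gtol=None, max_nfev=max_nfev)
            sse = float(np.sum(sol.fun ** 2))
            rows.append({"start": i, "sse": sse, "converged": bool(sol.success)})
            solutions.append(sol.x)
        except Exception as err:  # keep the multistart loop alive
            logger.warning("start %d failed: %s", i, err)
            rows.append({"start": i, "sse": np.inf, "converged": False})
            solutions.append(None)
    table = pd.DataFrame(rows)
    if not np.isfinite(table["sse"]).any():
        raise RuntimeError(
            f"all {n_starts} starts failed for model {model.model_id}:\n"
            f"{table}"
        )
    winner = int(table["sse"].idxmin())
    x_best = solutions[winner]
    best = {n: 10.0 ** v for n, v in zip(names, x_best)}
    fitted = model.with_parameters(best)
    equilibrate(fitted)
    by_channel = {
        c: float(np.sum(r ** 2))
        for c, r in channel_residuals(fitted, dataset, rtol=rtol,
                                      atol=atol).items()
    }
    return FitResult(
        model_id=model.model_id,
        parameter_names=names,
        params={**best},
        log10_params={n: float(v) for n, v in zip(names, x_best)},
        sse=float(table.loc[winner, "sse"]),
        sse_by_channel=by_channel,
        winner_start=winner,
        starts=table,
        seed=seed,
    )


def constrained_fit_model7(model7: ModelVariant, dataset: TimeSeriesDataset,
                           n_starts: int = 5, seed: int | None = 0,
                           **kwargs) -> FitResult:
    """Fit the Smad-turnover model with total R-Smad held constant.

    The synthesis rate is tied to the basal degradation flux at the
    pre-stimulus steady state (ksyn = kdeg_S2 * total Smad2), which is the
    flux-balance constraint; after fitting, the maximum deviation of total
    Smad2 over 24 hr is reported and checked against a 5 % band.
    """
    if "kdeg_S2" not in model7.network.parameters or \
            "ksyn_S2" not in model7.derived_parameters:
        raise ValueError("constrained fit requires a variant with "
                         "endogenous Smad turnover and the synthesis tie")

    t_grid = np.asarray(TSMAD_GRID)

    def constancy_penalty(variant: ModelVariant) -> np.ndarray:
        traj = simulate(variant,
                        StimulusProtocol(2.0, "long", horizon=1440.0),
                        t_grid, rtol=1e-6, atol=1e-9)
        total = traj.observe("Smad2_total")
        dev = np.abs(total / total[0] - 1.0)
        return 30.0 * np.maximum(0.0, dev - 0.04)

    result = fit_multistart(model7, dataset, n_starts=n_starts, seed=seed,
                            extra_residual_fn=constancy_penalty, **kwargs)
    fitted = model7.with_parameters(result.params)
    equilibrate(fitted)
    traj = simulate(fitted, StimulusProtocol(2.0, "long", horizon=1440.0),
                    np.linspace(0.0, 1440.0, 97))
    total = traj.observe("Smad2_total")
    max_dev = float(np.max(np.abs(total / total[0] - 1.0)))
    result.diagnostics["max_total_smad2_deviation"] = max_dev
    result.diagnostics["constraint_satisfied"] = bool(max_dev <= 0.05)
    if max_dev > 0.05:
        warnings.warn(
            f"constrained Model {model7.model_id} fit: total Smad2 deviates "
            f"{100 * max_dev:.1f}% over 24 hr (constraint infeasible at the "
            f"fitted parameters)", RuntimeWarning)
    return result


# -- model rejection -------------------------------------------------------

def _systematic_misfit(mean_res: np.ndarray, sem: np.ndarray) -> bool:
    """Does a replicate-mean residual sequence show systematic misfit?

    A time point deviates significantly when its mean residual exceeds
    twice the replicate standard error (floored at 2 % of the data scale,
    which keeps the check meaningful for noise-free data).  The pattern is
    called systematic when at least three points deviate significantly and
    the significant deviations are predominantly one-sided -- a sign-run
    structure that replicate noise alone essentially never produces.
    """
    mean_res = np.asarray(mean_res)
    n = mean_res.size
    if n < 4:
        return False
    floor = 0.02 * max(float(np.max(np.abs(mean_res))), 1e-12)
    sem = np.maximum(np.asarray(sem), floor)
    sig = np.abs(mean_res) > 2.0 * sem
    n_sig = int(np.sum(sig))
    if n_sig < 3 or n_sig <= 0.25 * n:
        return False
    signs = np.sign(mean_res[sig])
    dominant = max(np.sum(signs > 0), np.sum(signs < 0))
    return dominant >= 0.7 * n_sig


def _model_channel_table(model: ModelVariant, dataset: TimeSeriesDataset
                         ) -> tuple[dict[str, float], dict[str, np.ndarray],
                                    dict[str, np.ndarray]]:
    """Per-channel SSE, replicate-mean residual sequence and per-time
    standard error of the mean, over the channels whose observable the
    model defines."""
    from .models import observable_weights
    have = set(observable_weights(model.network))
    usable = [c for c in dataset.channel_ids()
              if dataset.channels[c].observable in have]
    res = channel_residuals(model, dataset.subset(usable))
    sse, mean_res, sems = {}, {}, {}
    for cid in usable:
        sub = dataset.data[dataset.data["channel_id"] == cid].copy()
        sub = sub.assign(residual=res[cid])  # observed - simulated
        grp = sub.groupby("time")["residual"]
        mean_res[cid] = grp.mean().to_numpy()
        counts = grp.count().to_numpy()
        sems[cid] = grp.std(ddof=1).fillna(0.0).to_numpy() / np.sqrt(counts)
        sse[cid] = float(np.sum(res[cid] ** 2))
    return sse, mean_res, sems


def _flagged(sse: Mapping[str, float], mean_res: Mapping[str, np.ndarray],
             sems: Mapping[str, np.ndarray],
             best: Mapping[str, float], channels: Sequence[str],
             sse_ratio: float) -> dict[str, float]:
    out = {}
    for cid in channels:
        if cid not in sse:
            continue
        ratio = sse[cid] / best[cid] if best[cid] > 0 else np.inf
        if ratio > sse_ratio and _systematic_misfit(mean_res[cid],
                                                    sems[cid]):
            out[cid] = ratio
    return out


#: verdict stages: fit-quality channels first, then prediction channels in
#: the order the corresponding measurements entered the analysis
VERDICT_STAGES = (("pS", ("pSmad2_short", "pSmad2_long")),
                  ("T1R", ("T1R",)),
                  ("tS", ("Smad2_total",)),
                  ("PPM1A", ("PPM1A",)))


def compare_models(fits: Mapping[str, FitResult],
                   dataset: TimeSeriesDataset,
                   sse_ratio: float = 3.0,
                   refit: bool = True,
                   n_starts: int = 3,
                   seed: int | None = 0) -> pd.DataFrame:
    """Model-rejection table: which dataset rejects each candidate model.

    A channel flags a model when the model's SSE on it exceeds
    ``sse_ratio`` times the best model's SSE on that channel *and* the
    replicate-mean residual sequence is systematic (sign-run check).

    The verdict is staged the way the measurements entered the analysis:
    first the phospho-Smad2 fit quality, then the type-I receptor and
    total-Smad2 predictions.  A model flagged by a prediction channel is
    given the chance to accommodate it (``refit=True``): the channel is
    added to its fitting data and the model is refitted.  If the refit
    resolves the conflict without breaking the phospho fit, evaluation
    proceeds; the verdict is the first channel class the model cannot
    accommodate, or "None".
    """
    channel_ids = dataset.channel_ids()
    state: dict[str, dict] = {}
    for mid, fit in fits.items():
        model = assemble_model(mid).with_parameters(fit.params)
        equilibrate(model)
        sse, mean_res, sems = _model_channel_table(model, dataset)
        state[mid] = {"params": dict(fit.params), "sse": sse,
                      "resid": mean_res, "sem": sems}
    best = {cid: min(state[mid]["sse"][cid] for mid in fits
                     if cid in state[mid]["sse"])
            for cid in channel_ids}

    rows = []
    for mid in fits:
        verdict = "None"
        flagged_all: dict[str, float] = {}
        st = state[mid]
        fitted_channels = [c for c in FIT_CHANNELS_PPM1A
                           if c in st["sse"]] if "PPM1A" in st["sse"] \
            else [c for c in FIT_CHANNELS if c in st["sse"]]
        for label, chans in VERDICT_STAGES:
            present = [c for c in chans if c in st["sse"]]
            if not present:
                continue
            flags = _flagged(st["sse"], st["resid"], st["sem"], best,
                             present, sse_ratio)
            if not flags:
                continue
            flagged_all.update(flags)
            if label == "pS" or not refit:
                verdict = label
                break
            # accommodation attempt: refit with the offending channel(s)
            fitted_channels = fitted_channels + present
            model = assemble_model(mid)
            new_fit = fit_multistart(model,
                                     dataset.subset(fitted_channels),
                                     n_starts=n_starts, seed=seed)
            refitted = model.with_parameters(new_fit.params)
            equilibrate(refitted)
            sse, mean_res, sems = _model_channel_table(refitted, dataset)
            st = {"params": dict(new_fit.params), "sse": sse,
                  "resid": mean_res, "sem": sems}
            recheck = [c for c in (*FIT_CHANNELS, *present)
                       if c in st["sse"]]
            if _flagged(st["sse"], st["resid"], st["sem"], best, recheck,
                        sse_ratio):
                verdict = label  # the conflict cannot be reconciled
                break
            state[mid] = st  # accommodated; continue with refitted params
        row = {"model": mid, "verdict": verdict,
               "rejected_channels": ",".join(
                   sorted({VERDICT_LABELS.get(c, c) for c in flagged_all}))}
        row.update({f"sse_{cid}": state[mid]["sse"].get(cid, np.nan)
                    for cid in channel_ids})
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
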