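"""Stimulation and perturbation protocols, and trajectory extraction.

A :class:`StimulusProtocol` describes the ligand dose, the exposure mode
(continuous "long" exposure, or "short" exposure terminated by washout plus
type-I receptor kinase inhibition with SB-431542), and chemical
perturbations (MG132 proteasome inhibition, cycloheximide).  Washout is
implemented as a hard integration restart at ``t_wash``: extracellular
ligand is set to zero and the receptor kinase (Smad2 phosphorylation) is
disabled, since washing alone would leave pre-formed ligand-receptor
complexes signalling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import ModelVariant, equilibrate, observable_weights
from .network import moiety_matrix

TGFB_MASS_KDA = 25.0  # molecular mass of the active TGF-beta dimer

MG132 = "MG132"
CYCLOHEXIMIDE = "CYCLOHEXIMIDE"

#: default experimental comparison grid, minutes
EXPERIMENTAL_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 120.0, 240.0, 360.0,
                     480.0, 720.0, 1440.0)


def dose_convert(dose_ng_per_ml: float,
                 molecular_mass_kDa: float = TGFB_MASS_KDA) -> float:
    """Convert a TGF-beta dose from ng/ml to pM (2 ng/ml -> 80 pM)."""
    if molecular_mass_kDa <= 0:
        raise ValueError("molecular mass must be positive")
    if dose_ng_per_ml < 0:
        raise ValueError("dose must be non-negative")
    return dose_ng_per_ml * 1e3 / molecular_mass_kDa


@dataclass(frozen=True)
class StimulusProtocol:
    """Ligand dose/duration plus chemical perturbations.

    ``dose_ng_per_ml`` is converted to an extracellular relative
    concentration using the model's medium-to-cell volume ratio, so ligand
    depletion by receptor binding is representable at low doses.
    """

    dose_ng_per_ml: float = 2.0
    exposure: str = "long"          # "long" (continuous) | "short" (washout)
    t_wash: float = 30.0            # minutes
    perturbations: frozenset[str] = frozenset()
    horizon: float = 1440.0         # minutes

    def __post_init__(self) -> None:
        if self.dose_ng_per_ml < 0:
            raise ValueError("dose must be non-negative")
        if self.exposure not in ("long", "short"):
            raise ValueError("exposure must be 'long' or 'short'")
        if self.exposure == "short" and not self.t_wash < self.horizon:
            raise ValueError("t_wash must be below the horizon")

    def dose_pM(self) -> float:
        return dose_convert(self.dose_ng_per_ml)


LONG_EXPOSURE = StimulusProtocol(2.0, "long", horizon=1440.0)
SHORT_EXPOSURE = StimulusProtocol(2.0, "short", t_wash=30.0, horizon=1440.0)


@dataclass
class Trajectory:
    """Solver output on a time grid plus derived observables."""

    model_id: str
    times: np.ndarray               # minutes
    states: np.ndarray              # species x time, nM (nuclear relative)
    species_names: list[str]
    observables: pd.DataFrame       # time x observable, nM
    protocol: StimulusProtocol

    def species(self, name: str) -> np.ndarray:
        return self.states[self.species_names.index(name)]

    def observe(self, observable: str, normalize: str | None = None) -> np.ndarray:
        """One observable as a time series; optionally normalised to its
        own maximum or to its t=0 value (western-blot style)."""
        if observable not in self.observables.columns:
            raise KeyError(
                f"unknown observable {observable!r}; available: "
                f"{list(self.observables.columns)}"
            )
        y = self.observables[observable].to_numpy()
        if normalize is None:
            return y
        if normalize == "max":
            peak = float(np.max(y))
            return y / peak if peak > 0 else y
        if normalize == "t0":
            base = float(y[0])
            return y / base if base > 0 else y
        raise ValueError("normalize must be None, 'max' or 't0'")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (time_min, name, value, kind)."""
        rows = []
        for i, name in enumerate(self.species_names):
            rows.append(pd.DataFrame({
                "time_min": self.times, "name": name,
                "value": self.states[i], "kind": "species",
            }))
        for col in self.observables.columns:
            rows.append(pd.DataFrame({
                "time_min": self.times, "name": col,
                "value": self.observables[col].to_numpy(),
                "kind": "observable",
            }))
        return pd.concat(rows, ignore_index=True)


def apply_perturbation(model: ModelVariant, perturbation: str) -> ModelVariant:
    """Return a modified copy of the model; the original is untouched.

    MG132 zeroes the Smurf2-route degradation of nuclear phospho-Smad2 and
    nothing else (basal turnover of receptors, unphosphorylated Smad and
    PPM1A is untouched).  Cycloheximide halves every zeroth-order synthesis
    rate (translation block), including complex-induced synthesis.
    """
    if perturbation == MG132:
        has_reaction = any(r.name == "smurf_deg_pS2n"
                           for r in model.network.reactions)
        if not has_reaction:
            warnings.warn(
                f"MG132 is a no-op on model {model.model_id} "
                f"(no Smurf2-route phospho-Smad degradation)",
                RuntimeWarning,
            )
            return model.with_parameters({})
        return model.with_parameters({"kdeg_pSmad2": 0.0})
    if perturbation == CYCLOHEXIMIDE:
        overrides = {}
        for rxn in model.network.reactions:
            if not rxn.reactants:  # zeroth-order synthesis
                k = rxn.rate_constant
                overrides[k] = 0.5 * model.network.parameters[k]
        return model.with_parameters(overrides)
    raise ValueError(f"unknown perturbation {perturbation!r}")


def _integrate(network, y0, t_span, t_eval, rtol, atol):
    rhs = network.build_rhs()
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_span[0]
        raise RuntimeError(
            f"integration of {network.name} failed at t={last:.3g} min: "
            f"{sol.message}"
        )
    return sol


def simulate(model: ModelVariant, protocol: StimulusProtocol,
             times: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate a stimulation protocol from the pre-stimulus steady state.

    The model is equilibrated on demand (cached).  MG132/cycloheximide are
    applied as pre-treatments from t=0.  Short exposure restarts the
    integration at ``t_wash`` with zero extracellular ligand and the
    receptor kinase disabled.
    """
    if times is None:
        times = np.arange(0.0, protocol.horizon + 0.5, 1.0)
    times = np.asarray(times, dtype=float)
    if times.size and times[-1] > protocol.horizon + 1e-9:
        raise ValueError("requested times exceed the protocol horizon")

    work = model
    for pert in sorted(protocol.perturbations):
        work = apply_perturbation(work, pert)
    if work is not model or work.equilibrated_state is None:
        # perturbations are pre-treatments: they do not re-shape the
        # unstimulated steady state of the shared species, so the base
        # model's equilibrium is reused when available
        if model.equilibrated_state is None:
            equilibrate(model)
        work.equilibrated_state = model.equilibrated_state

    net = work.network
    y0 = np.array(work.equilibrated_state, dtype=float)
    dose_nM = protocol.dose_pM() * 1e-3
    y0[net.index["TGFB"]] = dose_nM * net.medium_ratio

    if protocol.exposure == "long" or protocol.dose_ng_per_ml == 0:
        sol = _integrate(net, y0, (0.0, protocol.horizon), times, rtol, atol)
        states = sol.y
        out_times = sol.t
    else:
        tw = protocol.t_wash
        pre_times = times[times <= tw]
        if pre_times.size == 0 or pre_times[-1] < tw:
            pre_times = np.append(pre_times, tw)
        sol1 = _integrate(net, y0, (0.0, tw), pre_times, rtol, atol)
        y_wash = sol1.y[:, -1].copy()
        # washout: ligand removed; SB-431542 blocks the receptor kinase
        y_wash[net.index["TGFB"]] = 0.0
        y_wash[net.index["TGFB_T2R"]] = 0.0
        net_post = net.with_parameters({"kphos": 0.0, "ka_ligand": 0.0})
        post_times = times[times > tw]
        eval_post = np.concatenate(([tw], post_times))
        sol2 = _integrate(net_post, y_wash, (tw, protocol.horizon),
                          eval_post, rtol, atol)
        mask1 = np.isin(sol1.t, times)
        states = np.hstack([sol1.y[:, mask1], sol2.y[:, 1:]])
        out_times = np.concatenate([sol1.t[mask1], sol2.t[1:]])

    weights = observable_weights(net)
    W = moiety_matrix(net, weights)
    obs = pd.DataFrame((W @ states).T, columns=list(weights),
                       index=out_times)
    obs.index.name = "time_min"
    return Trajectory(work.model_id, out_times, states,
                      net.species_names, obs, protocol)


def observe(trajectory: Trajectory, observable: str,
            normalize: str | None = None) -> np.ndarray:
    """Module-level convenience alias for :meth:`Trajectory.observe`."""
    return trajectory.observe(observable, normalize=normalize)
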