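"""Stochastic leaky integrate-and-fire model of P-unit electroreceptors.

The model chain is: threshold rectification of the input waveform (synaptic
transfer), dendritic low-pass filtering (extracts the amplitude modulation
from the carrier), and a noisy LIF spike generator with a spike-triggered
adaptation current and an absolute refractory period.

State equations (all voltages dimensionless, threshold at 1, reset at 0):

    tau_d dV_d/dt = -V_d + max(y(t), 0)
    tau_m dV_m/dt = -V_m + mu + beta * V_d - A + sqrt(2 D) xi(t)
    tau_a dA/dt   = -A
    V_m >= 1  ->  spike, V_m <- 0, A <- A + delta_a / tau_a,
                  V_m and A frozen for t_ref

Integration is forward Euler (Euler-Maruyama for the noise term) with a
0.05 ms time step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .stimgen import StimulusTrace, StimulusKind

#: default integration time step in seconds (0.05 ms)
DEFAULT_DT = 5e-5

#: initial transient discarded from every simulated trial, seconds
DEFAULT_DISCARD = 0.5


@dataclass
class PUnitParams:
    """The eight free parameters of the P-unit model plus the EOD frequency.

    Attributes
    ----------
    beta : float
        Input gain scaling the dendritic voltage (dimensionless).
    tau_m : float
        Membrane time constant of the spike generator, seconds.
    mu : float
        Constant bias current (dimensionless).
    D : float
        Intrinsic noise intensity (dimensionless^2 * s).
    tau_a : float
        Adaptation time constant, seconds.
    delta_a : float
        Adaptation increment per spike (dimensionless).
    tau_d : float
        Dendritic low-pass time constant, seconds.
    t_ref : float
        Absolute refractory period, seconds.
    f_eod : float
        EOD frequency of the simulated fish, Hz.
    """

    beta: float
    tau_m: float
    mu: float
    D: float
    tau_a: float
    delta_a: float
    tau_d: float
    t_ref: float
    f_eod: float
    cell: str = "model"

    #: spike threshold, fixed
    theta: float = 1.0
    #: reset voltage, fixed
    v_reset: float = 0.0

    def __post_init__(self):
        for name in ("tau_m", "tau_a", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.theta != 1.0 or self.v_reset != 0.0:
            raise ValueError("theta and v_reset are fixed at 1 and 0")

    def hash(self) -> str:
        payload = json.dumps(
            [self.beta, self.tau_m, self.mu, self.D, self.tau_a,
             self.delta_a, self.tau_d, self.t_ref, self.f_eod])
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SpikeData:
    """Per-trial spike times with their analysis context.

    Spike times are in seconds relative to the start of the analyzed window
    (i.e., after the initial transient has been discarded).
    """

    trials: list[np.ndarray]
    duration_s: float
    discard_s: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trials))

    def rate_hz(self) -> float:
        """Mean firing rate: total spike count over total analyzed duration."""
        total = self.n_trials * self.duration_s
        return self.n_spikes / total if total > 0 else 0.0

    def isis(self) -> np.ndarray:
        """Interspike intervals pooled over trials."""
        parts = [np.diff(t) for t in self.trials if len(t) >= 2]
        if not parts:
            return np.array([])
        return np.concatenate(parts)

    def to_csv(self, path) -> None:
        path = Path(path)
        rows = []
        for i, t in enumerate(self.trials):
            for s in t:
                rows.append((i, s))
        df = pd.DataFrame(rows, columns=["trial", "spike_time_s"])
        df.to_csv(path, index=False)
        sidecar = {"duration_s": self.duration_s, "discard_s": self.discard_s,
                   "n_trials": self.n_trials,
                   "meta": {k: v for k, v in self.meta.items()
                            if isinstance(v, (str, int, float, bool))}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path, duration_s: float | None = None) -> "SpikeData":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        discard = 0.0
        meta = {}
        n_trials = None
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            duration_s = sc.get("duration_s", duration_s)
            discard = sc.get("discard_s", 0.0)
            n_trials = sc.get("n_trials")
            meta = sc.get("meta", {})
        trials = []
        ids = sorted(df["trial"].unique()) if len(df) else []
        if n_trials is None:
            n_trials = len(ids)
        for i in range(n_trials):
            t = np.sort(df.loc[df["trial"] == i, "spike_time_s"].to_numpy())
            trials.append(t)
        if duration_s is None:
            duration_s = max((t[-1] for t in trials if len(t)), default=0.0)
        return cls(trials=trials, duration_s=float(duration_s),
                   discard_s=discard, meta=meta)


def threshold_rectify(y: np.ndarray) -> np.ndarray:
    """Set negative values to zero (synaptic transfer nonlinearity)."""
    return np.maximum(y, 0.0)


def dendritic_filter(y: np.ndarray, dt: float, tau_d: float) -> np.ndarray:
    """Rectify and low-pass filter an input waveform as the model dendrite.

    Forward-Euler update of tau_d dV_d/dt = -V_d + max(y, 0) from V_d(0)=0,
    identical to the filtering inside the spiking simulation.  The filter
    attenuates the carrier and carves out the amplitude modulation.
    """
    from scipy.signal import lfilter
    a = dt / tau_d
    return lfilter([a], [1.0, -(1.0 - a)], threshold_rectify(y))


@njit(cache=True)
def _integrate(y, dt, tau_m, mu, beta, tau_a, delta_a, tau_d, t_ref,
               noise, v0, a0):  # pragma: no cover - exercised via simulate()
    """Euler-forward integration of the full model over one trial.

    ``noise`` holds the per-step stochastic increments of V_m, already scaled
    by sqrt(2 D dt) / tau_m.  During the refractory period V_m and A are
    frozen; the dendritic filter keeps following the stimulus.
    Returns spike step indices.
    """
    n = y.shape[0]
    spikes = np.empty(n // max(1, int(t_ref / dt) + 1) + 1, dtype=np.int64)
    n_spikes = 0
    v = v0
    a = a0
    vd = 0.0
    ref_steps = int(round(t_ref / dt))
    ref_until = -1
    for i in range(n):
        yi = y[i]
        if yi < 0.0:
            yi = 0.0
        vd += dt / tau_d * (-vd + yi)
        if i < ref_until:
            continue
        a += dt / tau_a * (-a)
        v += dt / tau_m * (-v + mu + beta * vd - a) + noise[i]
        if v >= 1.0:
            if n_spikes >= spikes.shape[0]:
                grown = np.empty(spikes.shape[0] * 2, dtype=np.int64)
                grown[:n_spikes] = spikes[:n_spikes]
                spikes = grown
            spikes[n_spikes] = i
            n_spikes += 1
            v = 0.0
            a += delta_a / tau_a
            ref_until = i + 1 + ref_steps
    return spikes[:n_spikes]


def trial_rngs(seed: int, n_trials: int, start: int = 0
               ) -> list[np.random.Generator]:
    """Independent per-trial random streams spawned from one root seed.

    The trial index participates in the spawn key so that increasing
    ``n_trials`` never changes earlier trials.
    """
    return [np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(start + i,))) for i in range(n_trials)]


def _simulate_trial(params: PUnitParams, y: np.ndarray, dt: float,
                    rng: np.random.Generator, alpha_noise: float = 1.0
                    ) -> np.ndarray:
    """One trial; returns spike times in seconds on the stimulus grid."""
    n = len(y)
    d_eff = params.D * alpha_noise
    scale = np.sqrt(2.0 * d_eff * dt) / params.tau_m
    noise = rng.standard_normal(n) * scale if d_eff > 0 else np.zeros(n)
    v0 = rng.uniform(0.0, 1.0)
    a0 = 0.0
    if params.delta_a > 0:
        a0 = rng.normal(0.0, 0.02 * params.delta_a)
    idx = _integrate(y, dt, params.tau_m, params.mu, params.beta,
                     params.tau_a, params.delta_a, params.tau_d,
                     params.t_ref, noise, v0, a0)
    times = (idx + 1) * dt
    if not np.all(np.isfinite(times)):
        raise FloatingPointError("non-finite state during integration")
    return times


def simulate(params: PUnitParams, stimulus: StimulusTrace, n_trials: int,
             seed: int, discard_s: float = DEFAULT_DISCARD,
             alpha_noise: float = 1.0) -> SpikeData:
    """Simulate spiking responses of the model to a stimulus waveform.

    The stimulus must be sampled at the integration step (0.05 ms by
    default); its ``samples`` are the full input y(t) including the carrier.
    Each trial draws V_m(0) uniformly from [0, 1), jitters the initial
    adaptation level, and uses an independent noise stream.  The first
    ``discard_s`` seconds are removed from the returned spike times.
    """
    if len(stimulus.samples) == 0:
        raise ValueError("empty stimulus")
    dt = stimulus.dt
    duration = stimulus.duration_s - discard_s
    if duration <= 0:
        raise ValueError("stimulus shorter than the discarded transient")
    trials = []
    for rng in trial_rngs(seed, n_trials):
        t = _simulate_trial(params, stimulus.samples, dt, rng, alpha_noise)
        t = t[t > discard_s] - discard_s
        trials.append(t[t <= duration])
    return SpikeData(trials=trials, duration_s=duration, discard_s=discard_s,
                     meta={"params_hash": params.hash(), "seed": seed,
                           "stimulus_kind": stimulus.kind.value,
                           "contrast": stimulus.contrast})


def eod_carrier(f_eod: float, duration_s: float, dt: float = DEFAULT_DT
                ) -> StimulusTrace:
    """The fish's own EOD: a unit-amplitude cosine at f_eod."""
    n = int(round(duration_s / dt))
    t = np.arange(n) * dt
    return StimulusTrace(samples=np.cos(2.0 * np.pi * f_eod * t), dt=dt,
                         kind=StimulusKind.MULTI_FISH, contrast=0.0,
                         cutoff_hz=0.0, meta={"f_eod": f_eod})


def simulate_baseline(params: PUnitParams, duration_s: float, n_trials: int,
                      seed: int, dt: float = DEFAULT_DT,
                      discard_s: float = DEFAULT_DISCARD) -> SpikeData:
    """Baseline activity: the model driven by its own EOD alone."""
    stim = eod_carrier(params.f_eod, duration_s + discard_s, dt)
    return simulate(params, stim, n_trials, seed, discard_s=discard_s)


# ---------------------------------------------------------------------------
# parameter-table I/O (models.csv schema)

_CSV_COLUMNS = ["cell", "beta", "tau_m_ms", "mu", "D", "tau_a_ms",
                "delta_a", "tau_d_ms", "t_ref_ms", "eodf_hz"]


def params_to_frame(params_list: list[PUnitParams]) -> pd.DataFrame:
    rows = [{"cell": p.cell, "beta": p.beta, "tau_m_ms": p.tau_m * 1e3,
             "mu": p.mu, "D": p.D, "tau_a_ms": p.tau_a * 1e3,
             "delta_a": p.delta_a, "tau_d_ms": p.tau_d * 1e3,
             "t_ref_ms": p.t_ref * 1e3, "eodf_hz": p.f_eod}
            for p in params_list]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_params_csv(params_list: list[PUnitParams], path) -> None:
    params_to_frame(params_list).to_csv(path, index=False)


def read_params_csv(path) -> list[PUnitParams]:
    """Read a parameter table; validates units (ms columns) and positivity."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter CSV is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(PUnitParams(
            beta=float(row["beta"]), tau_m=float(row["tau_m_ms"]) * 1e-3,
            mu=float(row["mu"]), D=float(row["D"]),
            tau_a=float(row["tau_a_ms"]) * 1e-3,
            delta_a=float(row["delta_a"]),
            tau_d=float(row["tau_d_ms"]) * 1e-3,
            t_ref=float(row["t_ref_ms"]) * 1e-3,
            f_eod=float(row["eodf_hz"]), cell=str(row["cell"])))
    return out
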