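"""Furutsu-Novikov noise split: intrinsic noise as an equivalent stimulus.

A large fraction (90 % by default) of the model's intrinsic noise is
replaced by a band-limited RAM stimulus s_xi(t) (cutoff 300 Hz) while the
intrinsic noise intensity is scaled down to alpha_noise = 0.1 of its
original value.  The amplitude of s_xi is bisected until the ISI CV of the
driven model matches the CV of the original model's baseline activity; the
output rate and variability are then the same as at baseline, but the
susceptibilities can be estimated from cross-spectra between s_xi and the
spike train with a drastically improved signal-to-noise ratio — the
weak-stimulus limit that is inaccessible with an external RAM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stimgen import (StimulusTrace, StimulusKind, band_limited_noise_samples)
from .punit_model import (PUnitParams, SpikeData, DEFAULT_DT, DEFAULT_DISCARD,
                          simulate_baseline, _simulate_trial, trial_rngs)
from .spectral import SpectralConfig, SpectralAccumulator, bin_spikes, \
    bin_stimulus, Susceptibility2

#: cutoff frequency of the noise-as-signal RAM, Hz
SPLIT_CUTOFF_HZ = 300.0


@dataclass
class NoiseSplitResult:
    """Outcome of the CV-matched noise split."""

    alpha_noise: float
    amplitude: float  # contrast (std) of s_xi, fraction of EOD amplitude
    achieved_cv: float
    achieved_rate_hz: float
    target_cv: float
    target_rate_hz: float
    converged: bool
    bisection_trace: list = field(default_factory=list)
    s_xi: list = field(default_factory=list)  # per-trial StimulusTrace

    def to_json(self, path) -> None:
        payload = {
            "alpha_noise": self.alpha_noise, "amplitude": self.amplitude,
            "achieved_cv": self.achieved_cv,
            "achieved_rate_hz": self.achieved_rate_hz,
            "target_cv": self.target_cv,
            "target_rate_hz": self.target_rate_hz,
            "converged": self.converged,
            "bisection_trace": [[float(a), float(c)]
                                for a, c in self.bisection_trace],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _split_trial(params: PUnitParams, amplitude: float, duration_s: float,
                 rng: np.random.Generator, alpha_noise: float,
                 dt: float = DEFAULT_DT, discard_s: float = DEFAULT_DISCARD,
                 keep_stimulus: bool = False):
    """One noise-split trial: fresh RAM realization, reduced intrinsic noise.

    Returns (spike times after discard, AM samples after discard or None).
    """
    n = int(round((duration_s + discard_s) / dt))
    s_xi = band_limited_noise_samples(n, dt, SPLIT_CUTOFF_HZ, amplitude, rng)
    t = np.arange(n) * dt
    y = (1.0 + s_xi) * np.cos(2.0 * np.pi * params.f_eod * t)
    spikes = _simulate_trial(params, y, dt, rng, alpha_noise=alpha_noise)
    spikes = spikes[spikes > discard_s] - discard_s
    spikes = spikes[spikes <= duration_s]
    am = None
    if keep_stimulus:
        k = int(round(discard_s / dt))
        am = s_xi[k:k + int(round(duration_s / dt))]
    return spikes, am


def _cv_at_amplitude(params: PUnitParams, amplitude: float, eval_seed: int,
                     alpha_noise: float, eval_duration_s: float,
                     eval_trials: int, dt: float):
    """CV and rate of the split model at a given RAM amplitude.

    A fixed evaluation seed makes the bisection target a deterministic
    function of the amplitude.
    """
    isis = []
    count = 0
    for rng in trial_rngs(eval_seed, eval_trials):
        spk, _ = _split_trial(params, amplitude, eval_duration_s, rng,
                              alpha_noise, dt=dt)
        count += len(spk)
        if len(spk) >= 2:
            isis.append(np.diff(spk))
    rate = count / (eval_trials * eval_duration_s)
    if not isis:
        return np.nan, rate
    isis = np.concatenate(isis)
    m = isis.mean()
    return (isis.std() / m if m > 0 else np.nan), rate


def bisect_amplitude(params: PUnitParams, target_cv: float, eval_seed: int,
                     alpha_noise: float = 0.1, cv_tol: float = 0.01,
                     bracket: tuple[float, float] = (0.0, 0.5),
                     max_iter: int = 40, eval_duration_s: float = 10.0,
                     eval_trials: int = 4, dt: float = DEFAULT_DT
                     ) -> tuple[float, float, float, bool, list]:
    """Bisect the s_xi amplitude until the ISI CV matches the baseline CV.

    The CV of the split-driven model increases monotonically with the RAM
    amplitude over the bracketing range; sampling noise is averaged out by
    evaluating CV over ``eval_trials`` trials of ``eval_duration_s`` each.
    Returns (amplitude, achieved_cv, achieved_rate, converged, trace).
    """
    lo, hi = bracket
    trace = []
    cv_lo, _ = _cv_at_amplitude(params, lo, eval_seed, alpha_noise,
                                eval_duration_s, eval_trials, dt)
    cv_hi, _ = _cv_at_amplitude(params, hi, eval_seed, alpha_noise,
                                eval_duration_s, eval_trials, dt)
    trace.append((lo, cv_lo))
    trace.append((hi, cv_hi))
    if not (np.isfinite(cv_lo) and np.isfinite(cv_hi)):
        raise RuntimeError("bisection endpoints produced too few spikes to "
                           f"estimate a CV (trace: {trace})")
    if not (cv_lo <= target_cv <= cv_hi):
        raise RuntimeError(
            f"target CV {target_cv:.3f} is not bracketed by the CVs at "
            f"amplitudes {lo} ({cv_lo:.3f}) and {hi} ({cv_hi:.3f})")
    amp, cv, rate = hi, cv_hi, np.nan
    converged = False
    for _ in range(max_iter):
        amp = 0.5 * (lo + hi)
        cv, rate = _cv_at_amplitude(params, amp, eval_seed, alpha_noise,
                                    eval_duration_s, eval_trials, dt)
        trace.append((amp, cv))
        if np.isfinite(cv) and abs(cv - target_cv) <= cv_tol:
            converged = True
            break
        if not np.isfinite(cv) or cv < target_cv:
            lo = amp
        else:
            hi = amp
    return amp, cv, rate, converged, trace


def split_simulate(params: PUnitParams, duration_s: float, n_trials: int,
                   seed: int, alpha_noise: float = 0.1, cv_tol: float = 0.01,
                   dt: float = DEFAULT_DT,
                   baseline_duration_s: float = 30.0,
                   keep_stimulus: bool = True
                   ) -> tuple[SpikeData, NoiseSplitResult]:
    """Noise-split simulation with CV-matched RAM amplitude.

    A baseline run (full intrinsic noise, EOD carrier only) defines the
    target CV and rate; the s_xi amplitude is bisected against that target;
    the production run then simulates ``n_trials`` trials with a fresh RAM
    realization each, retaining the AM traces for cross-spectral estimation.
    """
    base = simulate_baseline(params, baseline_duration_s, 1, seed + 1, dt=dt)
    isis = base.isis()
    if len(isis) < 2:
        raise RuntimeError("baseline produced too few spikes for a CV")
    target_cv = float(isis.std() / isis.mean())
    target_rate = base.rate_hz()
    amp, cv, rate, converged, trace = bisect_amplitude(
        params, target_cv, eval_seed=seed + 2, alpha_noise=alpha_noise,
        cv_tol=cv_tol, dt=dt)
    if not converged:
        raise RuntimeError(
            f"bisection did not reach |CV - {target_cv:.3f}| <= {cv_tol} "
            f"within the iteration budget; closest CV {cv:.3f} at amplitude "
            f"{amp:.4f} (trace: {trace[-3:]})")
    trials = []
    stimuli = []
    for rng in trial_rngs(seed, n_trials):
        spk, am = _split_trial(params, amp, duration_s, rng, alpha_noise,
                               dt=dt, keep_stimulus=keep_stimulus)
        trials.append(spk)
        if keep_stimulus:
            stimuli.append(StimulusTrace(
                samples=am, dt=dt, kind=StimulusKind.NOISE_AM, contrast=amp,
                cutoff_hz=SPLIT_CUTOFF_HZ, seed=seed))
    spikes = SpikeData(trials=trials, duration_s=duration_s,
                       discard_s=DEFAULT_DISCARD,
                       meta={"params_hash": params.hash(), "seed": seed,
                             "stimulus_kind": "noise_split",
                             "alpha_noise": alpha_noise, "contrast": amp})
    # achieved stats from the production run itself
    prod_isis = spikes.isis()
    achieved_cv = float(prod_isis.std() / prod_isis.mean()) \
        if len(prod_isis) >= 2 else np.nan
    result = NoiseSplitResult(
        alpha_noise=alpha_noise, amplitude=amp, achieved_cv=achieved_cv,
        achieved_rate_hz=spikes.rate_hz(), target_cv=target_cv,
        target_rate_hz=target_rate, converged=converged,
        bisection_trace=trace, s_xi=stimuli)
    return spikes, result


def cross_spectra_vs_split(spikes: SpikeData, split: NoiseSplitResult,
                           cfg: SpectralConfig,
                           f_max_hz: float = SPLIT_CUTOFF_HZ
                           ) -> tuple:
    """First- and second-order susceptibility between s_xi and the spikes.

    Delegates to the spectral module with the retained noise-as-signal RAM
    as the stimulus.  Returns (Susceptibility1, Susceptibility2).
    """
    if len(split.s_xi) != spikes.n_trials:
        raise ValueError("trial count mismatch between spikes and retained "
                         "split stimuli")
    if split.amplitude <= 0:
        raise ValueError("degenerate zero-amplitude split stimulus: "
                         "susceptibility undefined")
    xs = bin_spikes(spikes, cfg)
    ss = [bin_stimulus(s.samples, s.dt, cfg) for s in split.s_xi]
    acc = SpectralAccumulator(cfg, f_max_hz=f_max_hz)
    for x, s in zip(xs, ss):
        acc.add_trial(x, s)
    return acc.chi1(), acc.chi2()


def split_susceptibility(params: PUnitParams, n_segments: int,
                         cfg: SpectralConfig | None = None, seed: int = 0,
                         alpha_noise: float = 0.1, cv_tol: float = 0.01,
                         f_max_hz: float = SPLIT_CUTOFF_HZ,
                         segments_per_trial: int = 10,
                         dt: float = DEFAULT_DT,
                         amplitude: float | None = None
                         ) -> tuple[SpectralAccumulator, NoiseSplitResult]:
    """Streaming noise-split susceptibility estimation.

    Runs trials of ``segments_per_trial`` FFT segments each (after the
    0.5 s transient) with a fresh RAM realization per trial, accumulating
    cross-spectra in constant memory until ``n_segments`` segments are
    collected.  If ``amplitude`` is given the bisection is skipped (useful
    for re-runs at a known matched amplitude).
    """
    if cfg is None:
        cfg = SpectralConfig(n_segments=n_segments)
    else:
        cfg.n_segments = n_segments
    base = simulate_baseline(params, 30.0, 1, seed + 1, dt=dt)
    isis = base.isis()
    target_cv = float(isis.std() / isis.mean())
    target_rate = base.rate_hz()
    trace = []
    converged = True
    if amplitude is None:
        amplitude, _, _, converged, trace = bisect_amplitude(
            params, target_cv, eval_seed=seed + 2, alpha_noise=alpha_noise,
            cv_tol=cv_tol, dt=dt)
        if not converged:
            raise RuntimeError("bisection did not converge; cannot stream "
                               "the susceptibility estimate")
    trial_dur = segments_per_trial * cfg.segment_duration_s
    acc = SpectralAccumulator(cfg, f_max_hz=f_max_hz)
    n_trials = int(np.ceil(n_segments / segments_per_trial))
    total_spikes = 0
    total_time = 0.0
    all_isis = []
    for rng in trial_rngs(seed, n_trials):
        spk, am = _split_trial(params, amplitude, trial_dur, rng,
                               alpha_noise, dt=dt, keep_stimulus=True)
        spikes = SpikeData(trials=[spk], duration_s=trial_dur)
        x = bin_spikes(spikes, cfg)[0]
        s = bin_stimulus(am, dt, cfg)
        acc.add_trial(x, s)
        total_spikes += len(spk)
        total_time += trial_dur
        if len(spk) >= 2:
            all_isis.append(np.diff(spk))
        if acc.n_segments >= n_segments:
            break
    isis = np.concatenate(all_isis) if all_isis else np.array([])
    achieved_cv = float(isis.std() / isis.mean()) if len(isis) >= 2 else np.nan
    result = NoiseSplitResult(
        alpha_noise=alpha_noise, amplitude=amplitude,
        achieved_cv=achieved_cv,
        achieved_rate_hz=total_spikes / total_time if total_time else np.nan,
        target_cv=target_cv, target_rate_hz=target_rate,
        converged=converged, bisection_trace=trace, s_xi=[])
    return acc, result
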