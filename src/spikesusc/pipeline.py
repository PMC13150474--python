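"""End-to-end runs: simulate, estimate susceptibilities, SI tables, sweeps.

Thin orchestration over the stimulus, model, spectral and metrics modules.
All entry points are deterministic functions of a root seed; long
second-order estimates stream over segment blocks in constant memory.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stimgen import band_limited_noise_samples
from .punit_model import (PUnitParams, SpikeData, DEFAULT_DT, DEFAULT_DISCARD,
                          simulate_baseline, _simulate_trial, trial_rngs)
from .spectral import (SpectralConfig, SpectralAccumulator, bin_spikes,
                       bin_stimulus, Susceptibility2)
from . import metrics

logger = logging.getLogger(__name__)


def ram_susceptibility(params: PUnitParams, contrast: float,
                       n_segments: int, seed: int,
                       cutoff_hz: float = 300.0,
                       cfg: SpectralConfig | None = None,
                       f_max_hz: float | None = None,
                       segments_per_trial: int = 10,
                       dt: float = DEFAULT_DT,
                       direct: bool = False) -> SpectralAccumulator:
    """Susceptibilities of a model cell driven by a RAM stimulus.

    Each trial uses a fresh noise realization; after the 0.5 s transient,
    ``segments_per_trial`` FFT segments are taken per trial and cross-spectra
    are accumulated until ``n_segments`` segments are collected.  With
    ``direct=True`` the noise is added to the EOD instead of modulating it
    (ampullary-style stimulation); cross-spectra are always computed against
    the noise waveform s(t) itself.
    """
    if cfg is None:
        cfg = SpectralConfig(n_segments=n_segments)
    else:
        cfg.n_segments = n_segments
    if f_max_hz is None:
        f_max_hz = min(cutoff_hz, cfg.nyquist_hz / 2.0)
    trial_dur = segments_per_trial * cfg.segment_duration_s
    n_steps = int(round((trial_dur + DEFAULT_DISCARD) / dt))
    k0 = int(round(DEFAULT_DISCARD / dt))
    t = np.arange(n_steps) * dt
    carrier = np.cos(2.0 * np.pi * params.f_eod * t)
    acc = SpectralAccumulator(cfg, f_max_hz=f_max_hz)
    n_trials = int(np.ceil(n_segments / segments_per_trial))
    for rng in trial_rngs(seed, n_trials):
        s = band_limited_noise_samples(n_steps, dt, cutoff_hz, contrast, rng)
        y = s + carrier if direct else (1.0 + s) * carrier
        spk = _simulate_trial(params, y, dt, rng)
        spk = spk[spk > DEFAULT_DISCARD] - DEFAULT_DISCARD
        spk = spk[spk <= trial_dur]
        spikes = SpikeData(trials=[spk], duration_s=trial_dur)
        x = bin_spikes(spikes, cfg)[0]
        sv = bin_stimulus(s[k0:k0 + int(round(trial_dur / dt))], dt, cfg)
        acc.add_trial(x, sv)
        if acc.n_segments >= n_segments:
            break
    return acc


def si_of_chi2(chi2: Susceptibility2, r_hz: float) -> metrics.SIResult:
    """Susceptibility index of a second-order susceptibility matrix."""
    proj = metrics.project_diagonal(chi2)
    return metrics.susceptibility_index(proj, r_hz)


def _mean_rate_vector(spikes: SpikeData, bin_dt: float) -> np.ndarray:
    cfg = SpectralConfig(bin_dt=bin_dt, nfft=2, n_segments=None)
    xs = bin_spikes(spikes, cfg)
    return np.mean(xs, axis=0)


def rate_psd(spikes: SpikeData, bin_dt: float = 5e-4
             ) -> tuple[np.ndarray, np.ndarray]:
    """Single-segment power spectral density of the trial-averaged rate.

    Uses the full trial length as one rectangular-window segment, so the
    frequency resolution is 1 / duration.  Suitable for reading off peak
    amplitudes at known stimulus frequencies via
    :func:`spikesusc.metrics.spectrum_peaks`.
    """
    x = _mean_rate_vector(spikes, bin_dt)
    n = len(x)
    spec = np.fft.rfft(x - x.mean())
    psd = (bin_dt / n) * np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, bin_dt)
    return freqs, psd


def two_sine_response(params: PUnitParams, contrast: float, df1: float,
                      df2: float, n_trials: int, seed: int,
                      duration_s: float = 2.0, dt: float = DEFAULT_DT,
                      bin_dt: float = 5e-4, mode: str = "beats") -> dict:
    """Response peak amplitudes under two-frequency stimulation.

    With ``mode="beats"`` the model is driven by its own EOD plus two
    foreign EODs at f_eod + df1 and f_eod + df2, both at the given contrast
    (the communication setting; the beats at df1 and df2 are emergent).
    With ``mode="am"`` the EOD is amplitude-modulated directly with two
    sinusoids at df1 and df2.  The two settings agree to first order in the
    contrast, but a superposed foreign EOD additionally distorts the
    envelope at second order, so the "am" mode isolates the cell's own
    quadratic response.  Returns the rate-spectrum peak amplitudes (Hz) at
    df1 and df2 and at their difference and sum; frequencies are snapped to
    the spectral grid of the trial duration.
    """
    res = 1.0 / duration_s
    df1 = round(df1 / res) * res
    df2 = round(df2 / res) * res
    n_steps = int(round((duration_s + DEFAULT_DISCARD) / dt))
    t = np.arange(n_steps) * dt
    if mode == "beats":
        y = (np.cos(2.0 * np.pi * params.f_eod * t)
             + contrast * np.cos(2.0 * np.pi * (params.f_eod + df1) * t)
             + contrast * np.cos(2.0 * np.pi * (params.f_eod + df2) * t))
    elif mode == "am":
        s = (contrast * np.cos(2.0 * np.pi * df1 * t)
             + contrast * np.cos(2.0 * np.pi * df2 * t))
        y = (1.0 + s) * np.cos(2.0 * np.pi * params.f_eod * t)
    else:
        raise ValueError("mode must be 'beats' or 'am'")
    trials = []
    for rng in trial_rngs(seed, n_trials):
        spk = _simulate_trial(params, y, dt, rng)
        spk = spk[spk > DEFAULT_DISCARD] - DEFAULT_DISCARD
        trials.append(spk[spk <= duration_s])
    spikes = SpikeData(trials=trials, duration_s=duration_s)
    freqs, psd = rate_psd(spikes, bin_dt)
    targets = np.array([df1, df2, abs(df2 - df1), df1 + df2])
    amps = metrics.spectrum_peaks(freqs, psd, targets)
    return {"contrast": contrast, "df1_hz": df1, "df2_hz": df2,
            "a_df1_hz": amps[0], "a_df2_hz": amps[1],
            "a_diff_hz": amps[2], "a_sum_hz": amps[3],
            "rate_hz": spikes.rate_hz()}


def two_sine_sweep(params: PUnitParams, contrasts, df1: float, df2: float,
                   n_trials: int, seed: int, duration_s: float = 2.0,
                   mode: str = "beats") -> pd.DataFrame:
    """Contrast sweep of the two-frequency response peaks."""
    rows = []
    for i, c in enumerate(contrasts):
        rows.append(two_sine_response(params, c, df1, df2, n_trials,
                                      seed + 1000 * i,
                                      duration_s=duration_s, mode=mode))
        logger.info("two-sine contrast %.3f done", c)
    return pd.DataFrame(rows)


def loglog_slope(x, y) -> float:
    """Least-squares slope of log(y) against log(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0)
    if ok.sum() < 2:
        return np.nan
    return float(np.polyfit(np.log(x[ok]), np.log(y[ok]), 1)[0])


def baseline_summary(params: PUnitParams, duration_s: float = 30.0,
                     seed: int = 0) -> metrics.BaselineStats:
    """Baseline statistics of a model cell from a single long trial."""
    spikes = simulate_baseline(params, duration_s, 1, seed)
    return metrics.baseline_stats(spikes, f_eod=params.f_eod)
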