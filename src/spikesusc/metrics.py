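"""Spike-train statistics, the susceptibility index SI(r), and cell typing.

Baseline statistics (rate, ISI coefficient of variation, vector strength,
serial ISI correlation) characterize the unstimulated cell; the response
modulation quantifies how strongly a noise stimulus drives it.  The
susceptibility index condenses the structure of a second-order
susceptibility matrix into one number: the height of the anti-diagonal
projection at the baseline firing rate relative to flanking reference
windows.  SI(r) > 1 indicates a ridge where f1 + f2 = r.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .punit_model import SpikeData
from .spectral import Susceptibility2


@dataclass
class BaselineStats:
    rate_hz: float
    cv: float
    vector_strength: float
    serial_corr_lag1: float
    duration_s: float


@dataclass
class ResponseStats:
    mean_rate_hz: float
    response_modulation_hz: float  # sigma_s, std over time of the mean rate


@dataclass
class DiagonalProjection:
    """Mean |chi_2| per anti-diagonal, indexed by the sum frequency f1+f2."""

    sum_freqs_hz: np.ndarray
    values: np.ndarray
    counts: np.ndarray  # number of matrix cells per anti-diagonal


@dataclass
class SIResult:
    f_peak_hz: float
    d_peak: float
    d_ref: float
    si: float


class CellClass(str, Enum):
    PUNIT = "punit"
    AMPULLARY = "ampullary"
    UNCLASSIFIED = "unclassified"


def baseline_stats(spikes: SpikeData, f_eod: float | None = None,
                   eod_trace=None) -> BaselineStats:
    """Baseline firing rate, ISI CV, vector strength and serial correlation.

    The rate is the spike count divided by the recording duration; the CV is
    the ISI standard deviation over the ISI mean.  Vector strength is the
    resultant length of spike phases within the EOD cycle; it needs either
    the EOD frequency or a recorded EOD trace (cycle boundaries from zero
    crossings).  The lag-one serial correlation is the Pearson correlation
    of consecutive ISI pairs; with fewer than 3 pairs or zero ISI variance
    it is undefined (NaN).
    """
    rate = spikes.rate_hz()
    isis = spikes.isis()
    if len(isis) < 1:
        cv = np.nan
    else:
        m = isis.mean()
        cv = isis.std() / m if m > 0 else np.nan
    # serial correlation of consecutive ISIs, pooled over trials
    pairs_a, pairs_b = [], []
    for t in spikes.trials:
        d = np.diff(t)
        if len(d) >= 2:
            pairs_a.append(d[:-1])
            pairs_b.append(d[1:])
    if pairs_a:
        a = np.concatenate(pairs_a)
        b = np.concatenate(pairs_b)
        # a (near-)constant ISI series carries no correlation information;
        # flag it rather than correlating representation noise
        degenerate = (a.std() <= 1e-9 * a.mean()
                      or b.std() <= 1e-9 * b.mean())
        if len(a) >= 3 and not degenerate:
            sc = float(np.corrcoef(a, b)[0, 1])
        else:
            sc = np.nan
    else:
        sc = np.nan
    vs = np.nan
    if eod_trace is not None and f_eod is None:
        # estimate the EOD frequency from zero crossings of the trace
        x = eod_trace.samples
        up = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
        if len(up) >= 2:
            f_eod = (len(up) - 1) / ((up[-1] - up[0]) * eod_trace.dt)
    if f_eod is not None:
        phases = []
        for t in spikes.trials:
            phases.append(2.0 * np.pi * np.mod(t * f_eod, 1.0))
        if phases:
            ph = np.concatenate(phases)
            if len(ph):
                vs = float(np.abs(np.mean(np.exp(1j * ph))))
    return BaselineStats(rate_hz=rate, cv=float(cv), vector_strength=vs,
                         serial_corr_lag1=sc, duration_s=spikes.duration_s)


def firing_rate(spikes: SpikeData, dt: float = 5e-4,
                kernel_sigma: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate from Gaussian-kernel convolution.

    Each spike contributes a normalized Gaussian of standard deviation
    ``kernel_sigma`` (1 ms default), so the integral of each single-trial
    rate equals its spike count.  Returns (time, rate).
    """
    if spikes.n_trials < 1:
        raise ValueError("need at least one trial")
    n = int(np.floor(spikes.duration_s / dt + 1e-9))
    t = np.arange(n) * dt
    half = max(int(np.ceil(4 * kernel_sigma / dt)), 1)
    k = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (k / kernel_sigma) ** 2)
    kernel /= kernel.sum() * dt
    rate = np.zeros(n)
    for spk in spikes.trials:
        x = np.zeros(n)
        if len(spk):
            idx = np.minimum((spk / dt).astype(int), n - 1)
            np.add.at(x, idx, 1.0)
        rate += np.convolve(x, kernel, mode="same")
    return t, rate / spikes.n_trials


def response_modulation(rate: np.ndarray) -> ResponseStats:
    """sigma_s: standard deviation over time of the trial-averaged rate."""
    return ResponseStats(mean_rate_hz=float(np.mean(rate)),
                         response_modulation_hz=float(np.std(rate)))


def project_diagonal(chi2: Susceptibility2) -> DiagonalProjection:
    """Project |chi_2| onto the diagonal by averaging anti-diagonals.

    Every matrix cell (f1, f2) contributes to the anti-diagonal with sum
    frequency f1 + f2, including the shortened ones near the corners.
    """
    mag = chi2.magnitude()
    m, n = mag.shape
    if m != n:
        raise ValueError("second-order susceptibility matrix must be square")
    i = np.arange(m)
    sum_idx = (i[:, None] + i[None, :]).ravel()
    finite = np.isfinite(mag.ravel())
    sums = np.bincount(sum_idx[finite], weights=mag.ravel()[finite],
                       minlength=2 * m - 1)
    counts = np.bincount(sum_idx[finite], minlength=2 * m - 1)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    sum_freqs = chi2.f1_hz[0] + chi2.f2_hz[0] + \
        (chi2.f1_hz[1] - chi2.f1_hz[0]) * np.arange(2 * m - 1) \
        if m > 1 else np.array([chi2.f1_hz[0] + chi2.f2_hz[0]])
    return DiagonalProjection(sum_freqs_hz=sum_freqs, values=vals,
                              counts=counts)


def susceptibility_index(proj: DiagonalProjection, r_hz: float,
                         peak_window_hz: float = 50.0) -> SIResult:
    """SI(r): ridge height of the diagonal projection at the baseline rate.

    f_peak is the argmax of D(f) within +-50 Hz of the baseline firing rate
    r; the reference floor is the average of D over 10 Hz wide windows 10 Hz
    to the left and right of the peak:
    D_ref = ( <D([f_peak-20, f_peak-10])> + <D([f_peak+10, f_peak+20])> ) / 2
    and SI = D(f_peak) / D_ref.  Window membership is evaluated on bin
    centers with closed intervals; argmax ties break toward the bin nearest
    r, then toward lower frequency.
    """
    f = proj.sum_freqs_hz
    d = proj.values
    need_lo, need_hi = r_hz - peak_window_hz - 20.0, r_hz + peak_window_hz + 20.0
    in_peak = (f >= r_hz - peak_window_hz) & (f <= r_hz + peak_window_hz)
    if not np.any(in_peak & np.isfinite(d)):
        raise ValueError(
            f"projection does not cover the peak search band "
            f"[{r_hz - peak_window_hz:.1f}, {r_hz + peak_window_hz:.1f}] Hz")
    cand = np.nonzero(in_peak & np.isfinite(d))[0]
    dmax = d[cand].max()
    ties = cand[d[cand] == dmax]
    if len(ties) > 1:
        dist = np.abs(f[ties] - r_hz)
        ties = ties[dist == dist.min()]
    peak = int(ties.min())
    f_peak = float(f[peak])
    windows = []
    for lo, hi in [(f_peak - 20.0, f_peak - 10.0),
                   (f_peak + 10.0, f_peak + 20.0)]:
        sel = (f >= lo) & (f <= hi) & np.isfinite(d)
        if not np.any(sel):
            raise ValueError(
                f"projection is missing the reference band "
                f"[{lo:.1f}, {hi:.1f}] Hz (need coverage of "
                f"[{need_lo:.1f}, {need_hi:.1f}] Hz)")
        windows.append(d[sel].mean())
    d_ref = 0.5 * (windows[0] + windows[1])
    d_peak = float(d[peak])
    return SIResult(f_peak_hz=f_peak, d_peak=d_peak, d_ref=float(d_ref),
                    si=d_peak / d_ref if d_ref > 0 else np.inf)


def spectrum_peaks(freqs: np.ndarray, psd: np.ndarray,
                   target_freqs, flank_hz: tuple[float, float] = (5.0, 15.0),
                   exclude_bins: int = 2) -> np.ndarray:
    """Amplitudes (Hz) of spectral peaks at target frequencies.

    The peak power is read at the bin nearest each target; a local noise
    floor — the median of the spectrum over the +-5 to 15 Hz flanks,
    excluding +-2 bins around the target — is subtracted, and the
    floor-corrected power is converted to the amplitude of the underlying
    sinusoid: a = 2 sqrt(S_peak * df) for a two-sided density S.
    """
    freqs = np.asarray(freqs)
    psd = np.asarray(psd)
    df = freqs[1] - freqs[0]
    nyq = freqs[-1]
    out = []
    for ft in np.atleast_1d(target_freqs):
        if ft > nyq:
            raise ValueError(f"target {ft} Hz is beyond the Nyquist "
                             f"frequency {nyq} Hz")
        k = int(np.argmin(np.abs(freqs - ft)))
        flank = (np.abs(freqs - ft) >= flank_hz[0]) & \
                (np.abs(freqs - ft) <= flank_hz[1]) & \
                (np.abs(np.arange(len(freqs)) - k) > exclude_bins)
        floor = np.median(psd[flank]) if np.any(flank) else 0.0
        p = max(psd[k] - floor, 0.0)
        out.append(2.0 * np.sqrt(p * df))
    return np.array(out)


#: classification thresholds (table-driven defaults, as printed)
PUNIT_THRESHOLDS = {"vs_min": 0.7, "vs_max": 0.95, "rate_min_hz": 30.0,
                    "sc_max": 0.0, "cv_base_max": 1.5, "cv_stim_max": 2.0}
AMPULLARY_THRESHOLDS = {"vs_max": 0.15, "rate_min_hz": 10.0,
                        "cv_base_max": 0.18, "cv_stim_max": 1.0,
                        "sigma_s_max_hz": 80.0}


def classify_cell(b: BaselineStats, resp: ResponseStats, cv_stim: float,
                  punit_thresholds: dict | None = None,
                  ampullary_thresholds: dict | None = None) -> CellClass:
    """Classify a recording as P-unit, ampullary afferent, or neither.

    P-units: vector strength between 0.7 and 0.95, baseline rate above
    30 Hz, negative lag-one serial ISI correlation, baseline CV below 1.5
    and CV during stimulation below 2.  Ampullary cells: vector strength
    below 0.15, baseline rate above 10 Hz, baseline CV below 0.18, CV
    during stimulation below 1.0, response modulation below 80 Hz.
    """
    pt = PUNIT_THRESHOLDS if punit_thresholds is None else punit_thresholds
    at = (AMPULLARY_THRESHOLDS if ampullary_thresholds is None
          else ampullary_thresholds)
    vals = [b.rate_hz, b.cv, b.vector_strength, b.serial_corr_lag1, cv_stim,
            resp.response_modulation_hz]
    if not all(np.isfinite(v) for v in vals[:2]):
        return CellClass.UNCLASSIFIED
    if (np.isfinite(b.vector_strength)
            and pt["vs_min"] <= b.vector_strength <= pt["vs_max"]
            and b.rate_hz > pt["rate_min_hz"]
            and np.isfinite(b.serial_corr_lag1)
            and b.serial_corr_lag1 < pt["sc_max"]
            and b.cv < pt["cv_base_max"]
            and np.isfinite(cv_stim) and cv_stim < pt["cv_stim_max"]):
        return CellClass.PUNIT
    vs_ok = (not np.isfinite(b.vector_strength)) or \
        b.vector_strength < at["vs_max"]
    if (vs_ok and b.rate_hz > at["rate_min_hz"]
            and b.cv < at["cv_base_max"]
            and np.isfinite(cv_stim) and cv_stim < at["cv_stim_max"]
            and np.isfinite(resp.response_modulation_hz)
            and resp.response_modulation_hz < at["sigma_s_max_hz"]):
        return CellClass.AMPULLARY
    return CellClass.UNCLASSIFIED
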