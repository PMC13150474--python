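"""Segment-averaged spectra and susceptibilities of spike trains.

Spike trains are converted to rate-coded binary vectors (1/dt in bins that
contain a spike), cut into non-overlapping rectangular-window FFT segments,
and averaged cross-spectra yield the first-order susceptibility (transfer
function)

    chi_1(w) = S_xs(w) / S_ss(w),        S_xs(w) = dt/N <X(w) S*(w)>

and the second-order susceptibility (normalized cross-bispectrum)

    chi_2(w1, w2) = S_xss(w1, w2) / (2 S_ss(w1) S_ss(w2)),
    S_xss(w1, w2) = dt^2/N <X(w1+w2) S*(w1) S*(w2)>,

which quantifies the response at the sum of two stimulus frequencies.
Susceptibilities are reported per percent stimulus contrast (Hz/% and
Hz/%^2): cross-spectra are computed on the fractional-contrast signal and
converted by 1e-2 and 1e-4, respectively.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .punit_model import SpikeData

logger = logging.getLogger(__name__)

#: conversion of chi_1 from Hz per fractional contrast to Hz per percent
PCT1 = 1e-2
#: conversion of chi_2 from Hz per fractional contrast squared to Hz/%^2
PCT2 = 1e-4


@dataclass
class SpectralConfig:
    """Segmenting rules for all spectral estimates.

    Defaults follow the standard recording-scale analysis: 0.5 ms bins,
    512-sample segments (256 ms, about 4 Hz resolution), no window, no
    overlap, 100 segments.
    """

    bin_dt: float = 5e-4
    nfft: int = 512
    n_segments: int | None = 100
    discard_s: float = 0.0

    def __post_init__(self):
        if self.nfft < 2 or (self.nfft & (self.nfft - 1)) != 0:
            raise ValueError("nfft must be a power of two")
        if self.bin_dt <= 0:
            raise ValueError("bin_dt must be positive")

    @property
    def segment_duration_s(self) -> float:
        return self.nfft * self.bin_dt

    @property
    def resolution_hz(self) -> float:
        return 1.0 / self.segment_duration_s

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.bin_dt)

    def freqs(self) -> np.ndarray:
        """One-sided frequency axis of a segment FFT."""
        return np.fft.rfftfreq(self.nfft, self.bin_dt)

    def stimulation_time_s(self, n_segments: int | None = None) -> float:
        """Total stimulation time needed for a number of FFT segments."""
        n = self.n_segments if n_segments is None else n_segments
        return n * self.segment_duration_s


@dataclass
class Susceptibility1:
    """First-order susceptibility (transfer function) in Hz per % contrast."""

    freqs_hz: np.ndarray
    values: np.ndarray  # complex
    n_segments: int

    def gain(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class Susceptibility2:
    """Second-order susceptibility over the positive (f1, f2) quadrant.

    ``values[i, j]`` is chi_2 at (f1_hz[i], f2_hz[j]) in Hz/%^2; the
    magnitude is exactly symmetric in f1 and f2.
    """

    f1_hz: np.ndarray
    f2_hz: np.ndarray
    values: np.ndarray  # complex matrix
    n_segments: int
    contrast: float = 0.0

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_csv(self, path) -> None:
        """Long-form CSV (f1_hz, f2_hz, re, im, abs) plus JSON sidecar."""
        path = Path(path)
        f1, f2 = np.meshgrid(self.f1_hz, self.f2_hz, indexing="ij")
        df = pd.DataFrame({
            "f1_hz": f1.ravel(), "f2_hz": f2.ravel(),
            "re": self.values.real.ravel(), "im": self.values.imag.ravel(),
            "abs": np.abs(self.values).ravel()})
        df.to_csv(path, index=False)
        sidecar = {"n_segments": self.n_segments, "contrast": self.contrast,
                   "units": "Hz/%^2"}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "Susceptibility2":
        path = Path(path)
        df = pd.read_csv(path)
        f1 = np.unique(df["f1_hz"].to_numpy())
        f2 = np.unique(df["f2_hz"].to_numpy())
        vals = (df["re"].to_numpy() + 1j * df["im"].to_numpy()
                ).reshape(len(f1), len(f2))
        sc = json.loads(path.with_suffix(".json").read_text())
        return cls(f1_hz=f1, f2_hz=f2, values=vals,
                   n_segments=int(sc["n_segments"]),
                   contrast=float(sc.get("contrast", 0.0)))


def bin_spikes(spikes: SpikeData, cfg: SpectralConfig) -> list[np.ndarray]:
    """Rate-coded binary vectors: 1/bin_dt where a spike occurred, else 0.

    Two spikes in one bin count once (binary coding); a warning is logged.
    The mean of each vector approximates the trial's firing rate.
    """
    n_bins = int(np.floor(spikes.duration_s / cfg.bin_dt + 1e-9))
    out = []
    n_collisions = 0
    for t in spikes.trials:
        x = np.zeros(n_bins)
        if len(t):
            if t.min() < 0 or t.max() > spikes.duration_s:
                raise ValueError("spike times outside the trial duration")
            idx = np.minimum((t / cfg.bin_dt).astype(int), n_bins - 1)
            uniq = np.unique(idx)
            n_collisions += len(idx) - len(uniq)
            x[uniq] = 1.0 / cfg.bin_dt
        out.append(x)
    if n_collisions:
        logger.warning("%d spikes shared a %g ms bin with another spike and "
                       "were counted once", n_collisions, cfg.bin_dt * 1e3)
    return out


def bin_stimulus(samples: np.ndarray, dt: float, cfg: SpectralConfig
                 ) -> np.ndarray:
    """Down-sample a stimulus to the spike-bin grid by averaging within bins."""
    ratio = cfg.bin_dt / dt
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError("bin_dt must be an integer multiple of the "
                         "stimulus dt")
    if r == 1:
        return samples.copy()
    n = (len(samples) // r) * r
    return samples[:n].reshape(-1, r).mean(axis=1)


def _iter_segments(x: np.ndarray, cfg: SpectralConfig):
    start = int(round(cfg.discard_s / cfg.bin_dt))
    n_seg = (len(x) - start) // cfg.nfft
    for k in range(max(n_seg, 0)):
        a = start + k * cfg.nfft
        yield x[a:a + cfg.nfft]


def segment_ffts(xs: list[np.ndarray], cfg: SpectralConfig) -> np.ndarray:
    """FFTs of non-overlapping segments, concatenated in trial order.

    After the per-trial discard, each trial is cut into ``nfft``-sample
    rectangular segments (no overlap, no detrending).  Segments never span a
    trial boundary.  The result is truncated to the first ``n_segments``;
    fewer available segments raise an error naming the available count.
    """
    segs = []
    for x in xs:
        for seg in _iter_segments(x, cfg):
            segs.append(np.fft.rfft(seg))
            if cfg.n_segments is not None and len(segs) >= cfg.n_segments:
                break
        if cfg.n_segments is not None and len(segs) >= cfg.n_segments:
            break
    if cfg.n_segments is not None and len(segs) < cfg.n_segments:
        raise ValueError(
            f"requested {cfg.n_segments} segments but only {len(segs)} "
            f"available")
    if not segs:
        raise ValueError("no complete segments available")
    return np.array(segs)


def power_spectrum(xs: list[np.ndarray] | np.ndarray, cfg: SpectralConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Segment-averaged power spectral density, S(w) = dt/N <|X(w)|^2>.

    Returns (freqs_hz, density).  The density is one-sided on the returned
    axis but scaled as the two-sided density (integrating the two-sided
    spectrum over all frequencies gives the second moment of the signal).
    """
    if isinstance(xs, np.ndarray) and xs.ndim == 1:
        xs = [xs]
    specs = segment_ffts(list(xs), cfg)
    dens = (cfg.bin_dt / cfg.nfft) * np.mean(np.abs(specs) ** 2, axis=0)
    return cfg.freqs(), dens


class SpectralAccumulator:
    """Streaming accumulator for chi_1 and chi_2 over many segments.

    Feed aligned (spike-vector, stimulus-vector) trials; cross-spectral sums
    are updated in constant memory so that 1e6-segment simulations can
    stream.  ``f_max_hz`` bounds the (f1, f2) grid of the second-order
    estimate; it must not exceed half the Nyquist frequency so that f1 + f2
    stays on the segment FFT axis.
    """

    def __init__(self, cfg: SpectralConfig, f_max_hz: float | None = None,
                 compute_chi2: bool = True):
        self.cfg = cfg
        freqs = cfg.freqs()
        self.freqs = freqs
        if f_max_hz is None:
            f_max_hz = cfg.nyquist_hz / 2.0
        if compute_chi2 and 2.0 * f_max_hz > cfg.nyquist_hz + 1e-9:
            raise ValueError("f1 + f2 would exceed the Nyquist frequency; "
                             "reduce f_max_hz")
        self.m = int(np.floor(f_max_hz / cfg.resolution_hz + 1e-9))
        self.compute_chi2 = compute_chi2
        n = len(freqs)
        self.n_segments = 0
        self._sxs = np.zeros(n, dtype=complex)
        self._sss = np.zeros(n)
        self._sxx = np.zeros(n)
        if compute_chi2:
            self._sxss = np.zeros((self.m, self.m), dtype=complex)
            # index matrix for X(w1 + w2)
            i = np.arange(1, self.m + 1)
            self._sum_idx = i[:, None] + i[None, :]

    def add_trial(self, x: np.ndarray, s: np.ndarray) -> None:
        if len(x) != len(s):
            raise ValueError("spike and stimulus vectors differ in length")
        cfg = self.cfg
        for seg_x, seg_s in zip(_iter_segments(x, cfg),
                                _iter_segments(s, cfg)):
            if (cfg.n_segments is not None
                    and self.n_segments >= cfg.n_segments):
                return
            X = np.fft.rfft(seg_x)
            S = np.fft.rfft(seg_s)
            self._sxs += X * np.conj(S)
            self._sss += np.abs(S) ** 2
            self._sxx += np.abs(X) ** 2
            if self.compute_chi2:
                Sc = np.conj(S[1:self.m + 1])
                # outer product first: a*b == b*a bitwise, which keeps the
                # accumulated matrix exactly symmetric under f1 <-> f2
                self._sxss += X[self._sum_idx] * (Sc[:, None] * Sc[None, :])
            self.n_segments += 1

    def _check(self):
        if self.n_segments == 0:
            raise ValueError("no segments accumulated")
        if (self.cfg.n_segments is not None
                and self.n_segments < self.cfg.n_segments):
            raise ValueError(
                f"requested {self.cfg.n_segments} segments but only "
                f"{self.n_segments} available")

    def s_ss(self) -> np.ndarray:
        self._check()
        return (self.cfg.bin_dt / self.cfg.nfft) * self._sss / self.n_segments

    def s_xx(self) -> np.ndarray:
        self._check()
        return (self.cfg.bin_dt / self.cfg.nfft) * self._sxx / self.n_segments

    def s_xs(self) -> np.ndarray:
        self._check()
        return (self.cfg.bin_dt / self.cfg.nfft) * self._sxs / self.n_segments

    def chi1(self) -> Susceptibility1:
        """First-order susceptibility in Hz/% at all nonzero-power bins."""
        sxs = self.s_xs()
        sss = self.s_ss()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.where(sss > 0, sxs / np.where(sss > 0, sss, 1.0),
                            np.nan + 0j)
        return Susceptibility1(freqs_hz=self.freqs, values=vals * PCT1,
                               n_segments=self.n_segments)

    def chi2(self) -> Susceptibility2:
        """Second-order susceptibility in Hz/%^2 over (0, f_max]^2."""
        if not self.compute_chi2:
            raise ValueError("accumulator was created with compute_chi2=False")
        self._check()
        cfg = self.cfg
        sxss = (cfg.bin_dt ** 2 / cfg.nfft) * self._sxss / self.n_segments
        # the estimator is symmetric in (f1, f2) analytically; averaging with
        # the transpose removes the last-bit rounding asymmetry of fused
        # floating-point multiplies so the symmetry holds exactly
        sxss = 0.5 * (sxss + sxss.T)
        sss = self.s_ss()[1:self.m + 1]
        denom = 2.0 * sss[:, None] * sss[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, sxss / np.where(denom > 0, denom, 1.0),
                            np.nan + 0j)
        f = self.freqs[1:self.m + 1]
        return Susceptibility2(f1_hz=f, f2_hz=f, values=vals * PCT2,
                               n_segments=self.n_segments)


def _accumulate(spike_vectors, stimulus_vectors, cfg, f_max_hz=None,
                compute_chi2=True) -> SpectralAccumulator:
    if len(spike_vectors) != len(stimulus_vectors):
        raise ValueError("trial count mismatch between spikes and stimuli")
    acc = SpectralAccumulator(cfg, f_max_hz=f_max_hz,
                              compute_chi2=compute_chi2)
    for x, s in zip(spike_vectors, stimulus_vectors):
        acc.add_trial(x, s)
    acc._check()
    return acc


def chi1(spike_vectors: list[np.ndarray], stimulus_vectors: list[np.ndarray],
         cfg: SpectralConfig) -> Susceptibility1:
    """First-order susceptibility from aligned spike/stimulus vectors."""
    return _accumulate(spike_vectors, stimulus_vectors, cfg,
                       compute_chi2=False).chi1()


def chi2(spike_vectors: list[np.ndarray], stimulus_vectors: list[np.ndarray],
         cfg: SpectralConfig, f_max_hz: float,
         quadrant: str = "sum") -> Susceptibility2:
    """Second-order susceptibility up to f_max.

    ``quadrant="sum"`` (default) is the positive quadrant where the response
    frequency is f1 + f2.  ``quadrant="difference"`` evaluates the mixed
    quadrant (f1 negative): the response frequency is f2 - f1 and the
    estimator uses X(w2 - w1) S(w1) S*(w2).
    """
    if quadrant == "sum":
        return _accumulate(spike_vectors, stimulus_vectors, cfg,
                           f_max_hz=f_max_hz).chi2()
    if quadrant != "difference":
        raise ValueError("quadrant must be 'sum' or 'difference'")
    if len(spike_vectors) != len(stimulus_vectors):
        raise ValueError("trial count mismatch between spikes and stimuli")
    m = int(np.floor(f_max_hz / cfg.resolution_hz + 1e-9))
    i = np.arange(1, m + 1)
    signed_diff = i[None, :] - i[:, None]  # response frequency f2 - f1
    diff_idx = np.abs(signed_diff)
    neg = signed_diff < 0
    sxss = np.zeros((m, m), dtype=complex)
    sss = np.zeros(cfg.nfft // 2 + 1)
    n_seg = 0
    for x, s in zip(spike_vectors, stimulus_vectors):
        for seg_x, seg_s in zip(_iter_segments(x, cfg),
                                _iter_segments(s, cfg)):
            if cfg.n_segments is not None and n_seg >= cfg.n_segments:
                break
            X = np.fft.rfft(seg_x)
            S = np.fft.rfft(seg_s)
            # X at negative response frequencies via Hermitian symmetry
            Xd = X[diff_idx]
            Xd[neg] = np.conj(Xd[neg])
            s1 = S[1:m + 1]
            sxss += Xd * (s1[:, None] * np.conj(s1)[None, :])
            sss += np.abs(S) ** 2
            n_seg += 1
    if n_seg == 0:
        raise ValueError("no complete segments available")
    if cfg.n_segments is not None and n_seg < cfg.n_segments:
        raise ValueError(f"requested {cfg.n_segments} segments but only "
                         f"{n_seg} available")
    sxss *= cfg.bin_dt ** 2 / cfg.nfft / n_seg
    sss *= cfg.bin_dt / cfg.nfft / n_seg
    sb = sss[1:m + 1]
    denom = 2.0 * sb[:, None] * sb[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, sxss / np.where(denom > 0, denom, 1.0),
                        np.nan + 0j)
    f = cfg.freqs()[1:m + 1]
    return Susceptibility2(f1_hz=f, f2_hz=f, values=vals * PCT2,
                           n_segments=n_seg)
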