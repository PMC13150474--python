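"""Stimulus synthesis for electroreceptor experiments.

Band-limited Gaussian white noise, random amplitude modulations (RAMs) of an
EOD carrier, direct-noise stimuli for ampullary afferents, and superpositions
of several fish's EODs (beats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np


class StimulusKind(str, Enum):
    NOISE_AM = "noise_am"
    RAM_CARRIER = "ram_carrier"
    DIRECT_NOISE = "direct_noise"
    MULTI_FISH = "multi_fish"


@dataclass
class StimulusTrace:
    """A sampled stimulus waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitude per time step (fraction of EOD amplitude).
    dt : float
        Sampling interval in seconds.
    kind : StimulusKind
        What the trace represents.
    contrast : float
        Standard deviation of the amplitude modulation relative to the EOD
        amplitude, as a dimensionless fraction (0.05 for 5 %).
    cutoff_hz : float
        Upper cutoff of the noise band; 0 for purely sinusoidal stimuli.
    seed : int or None
        Seed used to generate the trace, if stochastic.
    """

    samples: np.ndarray
    dt: float
    kind: StimulusKind
    contrast: float = 0.0
    cutoff_hz: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt

    def to_csv(self, path) -> None:
        """Write as two-column CSV (time_s, value) plus a JSON sidecar."""
        path = Path(path)
        arr = np.column_stack([self.time, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")
        sidecar = {
            "dt": self.dt,
            "kind": self.kind.value,
            "contrast": self.contrast,
            "cutoff_hz": self.cutoff_hz,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "StimulusTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            dt = float(sc["dt"])
            kind = StimulusKind(sc["kind"])
            contrast = float(sc["contrast"])
            cutoff = float(sc["cutoff_hz"])
            seed = sc.get("seed")
        else:
            t = arr[:, 0]
            dt = float(np.median(np.diff(t)))
            kind = StimulusKind.NOISE_AM
            contrast = float(np.std(arr[:, 1]))
            cutoff = 0.0
            seed = None
        return cls(samples=arr[:, 1].copy(), dt=dt, kind=kind,
                   contrast=contrast, cutoff_hz=cutoff, seed=seed)


@dataclass
class CarrierSpec:
    """EOD frequencies and contrasts for a multi-fish superposition.

    The receiver's own EOD has unit amplitude; each foreign fish contributes
    a cosine at its own EOD frequency scaled by its contrast at the position
    of the receiver.
    """

    f_eod: float
    foreign_freqs: list[float] = field(default_factory=list)
    foreign_contrasts: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.f_eod <= 0:
            raise ValueError("f_eod must be positive")
        if len(self.foreign_freqs) != len(self.foreign_contrasts):
            raise ValueError("foreign_freqs and foreign_contrasts must have "
                             "equal length")
        if any(f <= 0 for f in self.foreign_freqs):
            raise ValueError("all foreign frequencies must be positive")
        if any(c < 0 for c in self.foreign_contrasts):
            raise ValueError("contrasts must be non-negative")


def band_limited_noise_samples(n: int, dt: float, cutoff_hz: float,
                               std: float, rng: np.random.Generator
                               ) -> np.ndarray:
    """Gaussian white noise with a flat spectrum up to ``cutoff_hz``.

    Independent standard-normal real and imaginary parts are drawn for every
    positive frequency bin up to the cutoff; Hermitian symmetry is implied by
    the inverse real FFT. The DC component is zero and the trace is rescaled
    exactly to the requested standard deviation (the Fourier-domain draw only
    fixes it in expectation); the rescaling leaves the spectrum flat.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    freqs = np.fft.rfftfreq(n, dt)
    coeffs = np.zeros(len(freqs), dtype=complex)
    band = (freqs > 0) & (freqs <= cutoff_hz)
    m = int(band.sum())
    coeffs[band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(coeffs, n=n)
    if std > 0:
        s = x.std()
        if s > 0:
            x *= std / s
        else:  # cutoff below frequency resolution: no band to fill
            x[:] = 0.0
    else:
        x[:] = 0.0
    return x


def _n_samples(duration_s: float, dt_s: float) -> int:
    return int(round(duration_s / dt_s))


def make_band_limited_noise(cutoff_hz: float, duration_s: float, dt_s: float,
                            contrast: float, seed: int) -> StimulusTrace:
    """Band-limited Gaussian white-noise amplitude modulation s(t).

    Flat power for 0 < f <= cutoff_hz, zero mean, standard deviation equal
    to ``contrast`` exactly.
    """
    nyquist = 1.0 / (2.0 * dt_s)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz for dt={dt_s} s")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    n = _n_samples(duration_s, dt_s)
    rng = np.random.default_rng(seed)
    x = band_limited_noise_samples(n, dt_s, cutoff_hz, contrast, rng)
    return StimulusTrace(samples=x, dt=dt_s, kind=StimulusKind.NOISE_AM,
                         contrast=contrast, cutoff_hz=cutoff_hz, seed=seed)


def _check_carrier_freq(f_eod: float, dt: float) -> None:
    if f_eod >= 1.0 / (2.0 * dt):
        raise ValueError(
            f"carrier frequency {f_eod} Hz is at or above the Nyquist "
            f"frequency {1.0 / (2.0 * dt)} Hz")


def make_ram_carrier(noise: StimulusTrace, f_eod: float) -> StimulusTrace:
    """Random amplitude modulation of the EOD carrier: (1 + s(t)) cos(2π f_eod t)."""
    if noise.kind is not StimulusKind.NOISE_AM:
        raise ValueError("make_ram_carrier expects a noise_am trace")
    _check_carrier_freq(f_eod, noise.dt)
    t = noise.time
    y = (1.0 + noise.samples) * np.cos(2.0 * np.pi * f_eod * t)
    return StimulusTrace(samples=y, dt=noise.dt, kind=StimulusKind.RAM_CARRIER,
                         contrast=noise.contrast, cutoff_hz=noise.cutoff_hz,
                         seed=noise.seed, meta={"f_eod": f_eod})


def make_direct_noise(noise: StimulusTrace, f_eod: float) -> StimulusTrace:
    """Noise added directly to the EOD (ampullary stimulation): s(t) + cos(2π f_eod t)."""
    if noise.kind is not StimulusKind.NOISE_AM:
        raise ValueError("make_direct_noise expects a noise_am trace")
    _check_carrier_freq(f_eod, noise.dt)
    t = noise.time
    y = noise.samples + np.cos(2.0 * np.pi * f_eod * t)
    return StimulusTrace(samples=y, dt=noise.dt,
                         kind=StimulusKind.DIRECT_NOISE,
                         contrast=noise.contrast, cutoff_hz=noise.cutoff_hz,
                         seed=noise.seed, meta={"f_eod": f_eod})


def make_multi_fish(spec: CarrierSpec, duration_s: float, dt_s: float
                    ) -> StimulusTrace:
    """Superposition of the receiver's EOD with foreign fish EODs.

    y(t) = cos(2π f_eod t) + Σ_i c_i cos(2π f_i t).  Beat frequencies
    |f_i - f_eod| emerge from the superposition; they are not parameters.
    """
    nyquist = 1.0 / (2.0 * dt_s)
    for f in [spec.f_eod, *spec.foreign_freqs]:
        if f >= nyquist:
            raise ValueError(f"frequency {f} Hz is at or above Nyquist "
                             f"{nyquist} Hz")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = _n_samples(duration_s, dt_s)
    t = np.arange(n) * dt_s
    y = np.cos(2.0 * np.pi * spec.f_eod * t)
    for f, c in zip(spec.foreign_freqs, spec.foreign_contrasts):
        y += c * np.cos(2.0 * np.pi * f * t)
    return StimulusTrace(samples=y, dt=dt_s, kind=StimulusKind.MULTI_FISH,
                         contrast=float(sum(spec.foreign_contrasts)),
                         cutoff_hz=0.0, seed=None,
                         meta={"f_eod": spec.f_eod,
                               "foreign_freqs": list(spec.foreign_freqs),
                               "foreign_contrasts": list(spec.foreign_contrasts)})


def extract_am(trace: StimulusTrace, f_eod: float | None = None,
               lowpass_hz: float = 300.0) -> np.ndarray:
    """Recover the amplitude modulation of a carrier trace.

    Threshold-rectify the waveform, low-pass filter below the carrier, and
    rescale by the mean of a rectified unit cosine (1/pi) so that a constant
    carrier of unit amplitude yields an envelope of one.
    """
    from scipy.signal import butter, sosfiltfilt
    rect = np.maximum(trace.samples, 0.0)
    nyq = 1.0 / (2.0 * trace.dt)
    sos = butter(4, lowpass_hz / nyq, output="sos")
    env = sosfiltfilt(sos, rect) * np.pi
    return env
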