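"""Filtering, downsampling, Morlet wavelet transform and band-amplitude ratios.

Laser-Doppler skin-blood-flow (SkBF) recordings carry slow vasomotor
oscillations whose spectral content between 0.005 and 0.150 Hz is
conventionally split into physiological bands: endothelial-NO-independent
(0.005-0.010 Hz), endothelial-NO-dependent (0.01-0.02 Hz), neurogenic
(0.02-0.05 Hz) and myogenic (0.05-0.15 Hz).  The per-band "wavelet
amplitude" of a recording interval is expressed as a ratio: the mean Morlet
modulus over the band divided by the mean modulus over the whole
0.005-0.150 Hz range, which makes it invariant to the arbitrary flow units.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sp_fft

F_TOTAL_LO = 0.005
F_TOTAL_HI = 0.150

#: Band edges (Hz).  The four bands partition [0.005, 0.150].
DEFAULT_BANDS = {
    "eno_independent": (0.005, 0.010),
    "eno_dependent": (0.010, 0.020),
    "neurogenic": (0.020, 0.050),
    "myogenic": (0.050, 0.150),
}

#: The three bands the downstream phenotype tables report.
NAMED_BANDS = ("eno_independent", "eno_dependent", "neurogenic")

PHASES = ("baseline", "phase1", "phase2", "phase3")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (F_TOTAL_LO <= self.f_lo < self.f_hi <= F_TOTAL_HI):
            raise ValueError(
                f"band {self.name}: need {F_TOTAL_LO} <= f_lo < f_hi <= {F_TOTAL_HI}, "
                f"got ({self.f_lo}, {self.f_hi})"
            )


def default_bands() -> list[BandDefinition]:
    return [BandDefinition(n, lo, hi) for n, (lo, hi) in DEFAULT_BANDS.items()]


@dataclass
class Recording:
    """One subject's paired flow/temperature traces at a uniform rate."""

    subject_id: str
    rate_hz: float
    immersion_start_s: float
    flow: np.ndarray
    temp: np.ndarray

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.flow.shape != self.temp.shape or self.flow.ndim != 1:
            raise ValueError("flow and temp must be 1-D arrays of equal length")
        if not (self.rate_hz > 0):
            raise ValueError("rate_hz must be positive")
        if not (np.isfinite(self.flow).all() and np.isfinite(self.temp).all()):
            raise ValueError("non-finite samples in recording")
        if not (0 <= self.immersion_start_s < len(self.flow) / self.rate_hz):
            raise ValueError("immersion_start_s outside record")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.flow)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.flow) / self.rate_hz


@dataclass
class WaveletSpectrum:
    freqs_hz: np.ndarray       # descending
    times_s: np.ndarray
    amp: np.ndarray            # (n_freqs, n_times), |W| >= 0
    coi_mask: np.ndarray       # True where inside the cone of influence (unreliable)

    def __post_init__(self):
        if self.amp.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("amp dimensions must be (n_freqs, n_times)")


def moving_average(series, rate_hz: float, window_s: float = 60.0) -> np.ndarray:
    """Centered moving mean with windows that shrink at the edges.

    The window is rounded to an odd number of samples so the filter is
    exactly symmetric (an even window would shift every feature by half a
    sample).  Output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    n_win = int(round(window_s * rate_hz))
    if n_win < 1:
        raise ValueError("window_s * rate_hz must be >= 1")
    n_win = n_win if n_win % 2 == 1 else n_win + 1
    return (
        pd.Series(x).rolling(n_win, center=True, min_periods=1).mean().to_numpy()
    )


def downsample(series, rate_in: float = 200.0, rate_out: float = 5.0) -> np.ndarray:
    """Block-mean decimation (averaging is the anti-alias step)."""
    x = np.asarray(series, dtype=float)
    factor = rate_in / rate_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"rate_in/rate_out must be a positive integer, got {factor}")
    factor = int(round(factor))
    n_blocks = len(x) // factor
    if n_blocks == 0:
        raise ValueError("series shorter than one decimation block")
    return x[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)


def morlet_frequency_grid(
    f_min: float = F_TOTAL_LO,
    f_max: float = F_TOTAL_HI,
    voices_per_octave: int = 16,
) -> np.ndarray:
    """Log-spaced frequencies, descending, spanning [f_min, f_max]."""
    n_octaves = math.log2(f_max / f_min)
    n = int(math.floor(n_octaves * voices_per_octave)) + 1
    return f_max * 2.0 ** (-np.arange(n) / voices_per_octave)


def morlet_response(f_grid: np.ndarray, f_carrier: float, omega0: float = 6.0) -> np.ndarray:
    """Ridge profile of a unit-amplitude sinusoid across analysis frequencies.

    With the L1-style normalization used by :func:`cwt_morlet`, a unit
    cosine at ``f_carrier`` yields |W|(f) = exp(-(omega0*(f_carrier/f - 1))**2 / 2),
    peaking at 1 on the ridge regardless of carrier frequency.
    """
    r = f_carrier / np.asarray(f_grid, dtype=float)
    return np.exp(-0.5 * (omega0 * (r - 1.0)) ** 2)


def cwt_morlet(
    series,
    rate_hz: float,
    f_min: float = F_TOTAL_LO,
    f_max: float = F_TOTAL_HI,
    voices_per_octave: int = 16,
    omega0: float = 6.0,
) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform with frequency-flat ridge gain.

    The analytic Morlet filter bank is applied in the Fourier domain with an
    L1-style normalization: hat{psi}_s(w) = 2 * exp(-(s*w - omega0)^2 / 2) for
    w > 0, with the scale-frequency map f = omega0 / (2*pi*s).  A unit
    sinusoid then produces ridge amplitude 1 at every carrier frequency,
    which is what makes band-amplitude *ratios* meaningful.  The signal mean
    is removed first.  Samples within one e-folding time sqrt(2)*s of either
    record edge are flagged in the cone-of-influence mask.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with at least two samples")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in series")
    x = x - x.mean()
    n = x.size
    freqs, psi, coi, nfft = _filter_bank(n, rate_hz, f_min, f_max,
                                         voices_per_octave, omega0)
    xf = sp_fft.fft(x, nfft)
    amp = np.abs(sp_fft.ifft(xf[None, :] * psi, axis=1)[:, :n])
    times = np.arange(n) / rate_hz
    return WaveletSpectrum(freqs_hz=freqs, times_s=times, amp=amp, coi_mask=coi)


_BANK_CACHE: dict = {}


def _filter_bank(n, rate_hz, f_min, f_max, voices_per_octave, omega0):
    """Cached analytic Morlet filter bank and cone-of-influence mask."""
    key = (n, rate_hz, f_min, f_max, voices_per_octave, omega0)
    hit = _BANK_CACHE.get(key)
    if hit is not None:
        return hit
    # pad past the longest wavelet's e-folding support to curb wrap-around
    scales_max = omega0 / (2.0 * np.pi * f_min)
    pad = int(2.5 * scales_max * rate_hz)
    nfft = sp_fft.next_fast_len(n + pad)
    freqs = morlet_frequency_grid(f_min, f_max, voices_per_octave)
    w = 2.0 * np.pi * sp_fft.fftfreq(nfft, d=1.0 / rate_hz)
    scales = omega0 / (2.0 * np.pi * freqs)
    # filter bank: (n_freqs, nfft); analytic (positive frequencies only)
    arg = scales[:, None] * w[None, :]
    psi = np.where(w[None, :] > 0, 2.0 * np.exp(-0.5 * (arg - omega0) ** 2), 0.0)
    times = np.arange(n) / rate_hz
    efold = np.sqrt(2.0) * scales
    dist_edge = np.minimum(times[None, :], times[-1] - times[None, :])
    coi = dist_edge < efold[:, None]
    if len(_BANK_CACHE) > 8:  # keep memory bounded
        _BANK_CACHE.clear()
    _BANK_CACHE[key] = (freqs, psi, coi, nfft)
    return _BANK_CACHE[key]


def band_amplitude_ratio(
    spec: WaveletSpectrum,
    band: BandDefinition,
    interval: tuple[float, float],
) -> float:
    """Mean |W| over (band x interval) divided by mean |W| over the full range.

    Cone-of-influence samples are excluded from both means.  Returns NaN when
    no reliable sample remains.
    """
    t0, t1 = interval
    if not (t1 > t0):
        raise ValueError(f"empty interval [{t0}, {t1})")
    t_sel = (spec.times_s >= t0) & (spec.times_s < t1)
    if not t_sel.any():
        raise ValueError(f"interval [{t0}, {t1}) does not overlap the spectrum")
    f = spec.freqs_hz
    f_band = (f >= band.f_lo) & (f <= band.f_hi)
    f_tot = (f >= F_TOTAL_LO) & (f <= F_TOTAL_HI)
    good = ~spec.coi_mask[:, t_sel]
    sub = spec.amp[:, t_sel]
    band_vals = sub[f_band][good[f_band]]
    tot_vals = sub[f_tot][good[f_tot]]
    if band_vals.size == 0 or tot_vals.size == 0:
        return float("nan")
    denom = tot_vals.mean()
    if denom == 0:
        return float("nan")
    return float(band_vals.mean() / denom)


def phase_amplitudes(
    spec: WaveletSpectrum,
    segmentation,
    bands: list[BandDefinition] | None = None,
) -> pd.DataFrame:
    """Band-amplitude ratio per phase x band; missing phases yield NaN rows.

    ``segmentation`` provides ``intervals()`` mapping phase name to a
    (t0, t1) tuple or None (see civd_detect.PhaseSegmentation).
    """
    bands = bands if bands is not None else default_bands()
    out = pd.DataFrame(
        np.nan, index=list(PHASES), columns=[b.name for b in bands], dtype=float
    )
    for phase, iv in segmentation.intervals().items():
        if iv is None:
            continue
        for b in bands:
            out.loc[phase, b.name] = band_amplitude_ratio(spec, b, iv)
    return out
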