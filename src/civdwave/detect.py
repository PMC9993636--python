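"""CIVD landmark detection, temperature confirmation and phase segmentation.

During sustained local cold exposure, finger skin blood flow (SkBF) first
collapses (vasoconstriction), reaches a minimum, and in most subjects later
rebounds — the hunting reaction, or cold-induced vasodilation (CIVD).  A
CIVD event is confirmed when, after the flow minimum, the finger temperature
also reaches a minimum and then rises.  The recording is segmented into
baseline, phase 1 (cooling onset to minimum flow), phase 2 (minimum flow to
CIVD onset) and phase 3 (CIVD onset to maximum flow); wavelet band
amplitudes are then summarised per phase.

All landmark detection operates on the 60-s moving-averaged traces; the
wavelet transform is applied to the unsmoothed (downsampled) flow, since a
60-s boxcar would suppress the 0.02-0.15 Hz bands the analysis needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sigproc
from .sigproc import (
    NAMED_BANDS,
    PHASES,
    Recording,
    cwt_morlet,
    default_bands,
    downsample,
    moving_average,
    phase_amplitudes,
)


@dataclass(frozen=True)
class DetectConfig:
    """Tunable landmark-detection constants.

    slope_thresh is a *relative* rate: the CIVD onset requires the centered
    slope of the smoothed flow to exceed ``slope_thresh`` times the
    constriction range (baseline mean minus immersion minimum) per minute,
    which makes detection invariant to affine rescaling of the arbitrary
    flow units.
    """

    window_s: float = 60.0           # moving-average window
    slope_thresh: float = 0.05       # fraction of constriction range per minute
    slope_halfwin_s: float = 30.0    # centered-difference half window
    sustain_s: float = 60.0          # slope must stay above threshold this long
    temp_rise_c: float = 0.3         # temperature rise confirming CIVD
    phase2_cap_s: float = 600.0      # phase-2 bound when no onset is found
    analysis_rate_hz: float = 5.0    # downsample target before analysis


MISSING = float("nan")


@dataclass
class CIVDCall:
    """Detected landmarks; times are seconds after immersion start, NaN = absent."""

    present: bool
    t_minflow_s: float
    t_onset_sbf_s: float
    t_maxflow_s: float
    t_mintemp_s: float
    t_maxtemp_s: float
    min_temp_c: float
    mean_temp_15_35_c: float
    diagnostic: str = ""

    def __post_init__(self):
        if self.present:
            if not (self.t_minflow_s < self.t_onset_sbf_s < self.t_maxflow_s):
                raise ValueError("landmark ordering violated: need t_minflow < t_onset < t_maxflow")
            if not (self.t_mintemp_s >= self.t_minflow_s):
                raise ValueError("landmark ordering violated: need t_mintemp >= t_minflow")


@dataclass
class PhaseSegmentation:
    """Absolute-time [t0, t1) intervals; phase2/phase3 may be missing (None)."""

    baseline: tuple[float, float]
    phase1: tuple[float, float]
    phase2: tuple[float, float] | None
    phase3: tuple[float, float] | None

    def intervals(self) -> dict:
        return {
            "baseline": self.baseline,
            "phase1": self.phase1,
            "phase2": self.phase2,
            "phase3": self.phase3,
        }


def smoothing_window_samples(window_s: float, rate_hz: float) -> int:
    """Odd sample count actually used by the 60-s moving average."""
    n = int(round(window_s * rate_hz))
    return n if n % 2 == 1 else n + 1


def centered_slope(series_smoothed: np.ndarray, rate_hz: float, halfwin_s: float) -> np.ndarray:
    """Symmetric two-point slope (units per second); edges padded with NaN."""
    x = np.asarray(series_smoothed, dtype=float)
    k = int(round(halfwin_s * rate_hz))
    if k < 1 or 2 * k >= x.size:
        raise ValueError("slope half-window too large for series")
    out = np.full(x.size, np.nan)
    out[k:-k] = (x[2 * k:] - x[: x.size - 2 * k]) / (2 * k / rate_hz)
    return out


def find_flow_landmarks(
    flow_smoothed: np.ndarray,
    rate_hz: float,
    immersion_start_s: float,
    cfg: DetectConfig = DetectConfig(),
) -> tuple[float, float, float]:
    """Locate (t_minflow, t_onset_sbf, t_maxflow), seconds after immersion start.

    t_minflow is the earliest global minimum of the smoothed flow during
    immersion; the onset is the earliest later time where the centered slope
    exceeds the threshold for at least ``sustain_s``; t_maxflow is the
    earliest maximum after the onset.  Downstream landmarks are NaN when
    their condition never holds.  Ties break toward the earlier sample.
    """
    x = np.asarray(flow_smoothed, dtype=float)
    i_imm = int(round(immersion_start_s * rate_hz))
    if x.size - i_imm <= cfg.sustain_s * rate_hz:
        raise ValueError("immersion window shorter than cfg.sustain_s")
    imm = x[i_imm:]
    i_min = int(np.argmin(imm))  # argmin returns the first of ties
    t_minflow = i_min / rate_hz

    baseline_mean = x[:i_imm].mean() if i_imm > 0 else x[0]
    rng = baseline_mean - imm[i_min]
    if rng <= 0:
        return t_minflow, MISSING, MISSING
    thresh = cfg.slope_thresh * rng / 60.0  # units per second

    slope = centered_slope(x, rate_hz, cfg.slope_halfwin_s)[i_imm:]
    n_sustain = int(round(cfg.sustain_s * rate_hz))
    above = slope > thresh
    above[np.isnan(slope)] = False
    # earliest i strictly after i_min with `above` true on [i, i + n_sustain)
    tail = above[i_min + 1:]
    if tail.size < n_sustain:
        return t_minflow, MISSING, MISSING
    run = np.convolve(tail.astype(int), np.ones(n_sustain, dtype=int), "valid")
    hits = np.nonzero(run == n_sustain)[0]
    if hits.size == 0:
        return t_minflow, MISSING, MISSING
    i_onset = i_min + 1 + int(hits[0])
    t_onset = i_onset / rate_hz

    if i_onset + 1 >= imm.size:
        return t_minflow, MISSING, MISSING
    i_max = i_onset + 1 + int(np.argmax(imm[i_onset + 1:]))
    return t_minflow, t_onset, i_max / rate_hz


def detect_civd(recording: Recording, cfg: DetectConfig = DetectConfig()) -> CIVDCall:
    """Detect flow landmarks and confirm CIVD via the temperature rebound."""
    rate = recording.rate_hz
    flow_s = moving_average(recording.flow, rate, cfg.window_s)
    temp_s = moving_average(recording.temp, rate, cfg.window_s)
    i_imm = int(round(recording.immersion_start_s * rate))
    t_min, t_on, t_max = find_flow_landmarks(
        flow_s, rate, recording.immersion_start_s, cfg
    )

    imm_temp = temp_s[i_imm:]
    min_temp_c = float(imm_temp.min())
    # protocol clock: mean temperature between minutes 15 and 35 of the record
    lo, hi = int(round(15 * 60 * rate)), int(round(35 * 60 * rate))
    mean_temp = float(temp_s[lo:min(hi, temp_s.size)].mean())

    diagnostic = ""
    present = False
    t_mintemp = MISSING
    t_maxtemp = MISSING
    if np.ptp(recording.temp) == 0:
        diagnostic = "temperature trace is constant"
    elif not math.isnan(t_on):
        # temperature minimum at/after the flow minimum, then a sustained rise
        i_tmin_rel = int(round(t_min * rate))
        seg = imm_temp[i_tmin_rel:]
        j_min = int(np.argmin(seg))
        t_mintemp = (i_tmin_rel + j_min) / rate
        rise = seg[j_min:].max() - seg[j_min]
        if rise >= cfg.temp_rise_c:
            present = True
            t_maxtemp = (i_tmin_rel + j_min + int(np.argmax(seg[j_min:]))) / rate
        else:
            diagnostic = f"temperature rise {rise:.3f} C below {cfg.temp_rise_c} C"
            t_mintemp = MISSING
    else:
        diagnostic = "no sustained flow rebound (onset missing)"

    return CIVDCall(
        present=present,
        t_minflow_s=t_min,
        t_onset_sbf_s=t_on,
        t_maxflow_s=t_max,
        t_mintemp_s=t_mintemp,
        t_maxtemp_s=t_maxtemp,
        min_temp_c=min_temp_c,
        mean_temp_15_35_c=mean_temp,
        diagnostic=diagnostic,
    )


def segment_phases(
    call: CIVDCall,
    immersion_start_s: float,
    record_end_s: float,
    cfg: DetectConfig = DetectConfig(),
) -> PhaseSegmentation:
    """Turn landmarks into absolute-time phase intervals.

    Flow landmarks are used even for subjects whose temperature never
    confirmed a CIVD (their flow may still rebound).  When the onset is
    missing, phase 2 is capped at ``phase2_cap_s`` after the flow minimum and
    phase 3 is missing.
    """
    imm = immersion_start_s
    t_min_abs = imm + call.t_minflow_s
    baseline = (0.0, imm)
    phase1 = (imm, t_min_abs)
    if math.isnan(call.t_onset_sbf_s):
        p2_end = min(t_min_abs + cfg.phase2_cap_s, record_end_s)
        return PhaseSegmentation(baseline, phase1, (t_min_abs, p2_end), None)
    t_on_abs = imm + call.t_onset_sbf_s
    t_max_abs = imm + call.t_maxflow_s
    return PhaseSegmentation(
        baseline, phase1, (t_min_abs, t_on_abs), (t_on_abs, t_max_abs)
    )


@dataclass
class SubjectPhenotype:
    subject_id: str
    civd_present: bool
    min_temp_c: float
    mean_temp_15_35_c: float
    t_minflow_s: float
    t_onset_sbf_s: float
    t_maxflow_s: float
    amplitudes: pd.DataFrame  # phases x bands band-amplitude ratios

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "civd_present": self.civd_present,
            "min_temp_c": self.min_temp_c,
            "mean_temp_15_35_c": self.mean_temp_15_35_c,
            "t_minflow_s": self.t_minflow_s,
            "t_onset_sbf_s": self.t_onset_sbf_s,
            "t_maxflow_s": self.t_maxflow_s,
        }
        for band in NAMED_BANDS:
            for phase in PHASES:
                row[f"{band}_{phase}"] = self.amplitudes.loc[phase, band]
        return row


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # annotate which pipeline stage failed
        raise type(exc)(f"[{name}] {exc}") from exc


def summarize_subject(
    recording: Recording,
    bands=None,
    cfg: DetectConfig = DetectConfig(),
) -> SubjectPhenotype:
    """Full per-subject pipeline: smooth, detect, segment, CWT, band ratios."""
    rec = recording
    if rec.rate_hz > cfg.analysis_rate_hz:
        factor_ok = abs(rec.rate_hz / cfg.analysis_rate_hz % 1) < 1e-9
        if not factor_ok:
            raise ValueError("recording rate not an integer multiple of analysis rate")
        rec = Recording(
            subject_id=rec.subject_id,
            rate_hz=cfg.analysis_rate_hz,
            immersion_start_s=rec.immersion_start_s,
            flow=_stage("downsample", downsample, rec.flow, rec.rate_hz, cfg.analysis_rate_hz),
            temp=_stage("downsample", downsample, rec.temp, rec.rate_hz, cfg.analysis_rate_hz),
        )
    call = _stage("detect_civd", detect_civd, rec, cfg)
    seg = _stage("segment_phases", segment_phases, call, rec.immersion_start_s, rec.duration_s, cfg)
    # Detrend by the same 60-s moving average before the transform: the slow
    # constriction/rebound envelope otherwise radiates into the lowest band
    # and swamps the vasomotor oscillations the band ratios quantify.
    detrended = rec.flow - moving_average(rec.flow, rec.rate_hz, cfg.window_s)
    spec = _stage("cwt_morlet", cwt_morlet, detrended, rec.rate_hz)
    amps = _stage("phase_amplitudes", phase_amplitudes, spec, seg, bands or default_bands())
    return SubjectPhenotype(
        subject_id=rec.subject_id,
        civd_present=call.present,
        min_temp_c=call.min_temp_c,
        mean_temp_15_35_c=call.mean_temp_15_35_c,
        t_minflow_s=call.t_minflow_s,
        t_onset_sbf_s=call.t_onset_sbf_s,
        t_maxflow_s=call.t_maxflow_s,
        amplitudes=amps,
    )


def phenotype_table(recordings, bands=None, cfg: DetectConfig = DetectConfig()) -> pd.DataFrame:
    """Apply summarize_subject to a cohort; one row per subject."""
    rows = [summarize_subject(r, bands, cfg).to_row() for r in recordings]
    return pd.DataFrame(rows)
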