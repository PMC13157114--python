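"""Autonomic scoring: trough-to-peak skin conductance and event-locked HR.

SCRs are scored with the trough-to-peak rule: the valley is the trace
minimum 1000-4000 ms after stimulus onset, the peak the maximum within
1500-7500 ms restricted to samples after the valley, and the response
amplitude is peak minus valley. Responses below 0.02 uS are invalid
(amplitudes of exactly 0.02 uS count as valid), trials whose trace does
not span 7500 ms post-onset are excluded, and a participant enters the
SCR analysis only with at least five valid trials in every condition.

Heart rate is derived from RR intervals (60000/RR, beats per minute),
linearly interpolated to a uniform grid and summarized as
baseline-corrected window means (baseline -1000..0 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

VALLEY_WINDOW_MS = (1000.0, 4000.0)
PEAK_WINDOW_MS = (1500.0, 7500.0)
MIN_AMPLITUDE_US = 0.02
TRIAL_SPAN_MS = 7500.0

ATB_HR_WINDOWS = {
    "0-1000": (0.0, 1000.0),      # deceleration
    "1000-3000": (1000.0, 3000.0),  # acceleration
    "3000-7500": (3000.0, 7500.0),  # post-stimulus recovery
    "0-7500": (0.0, 7500.0),      # overall
}
VIEWING_HR_WINDOWS = {"0-3000": (0.0, 3000.0)}
HR_BASELINE_MS = (-1000.0, 0.0)


@dataclass
class ScrScore:
    trial_id: int
    valley_us: float
    valley_latency_ms: float
    peak_us: float
    peak_latency_ms: float
    amplitude_us: float
    valid: bool
    exclusion_reason: str  # below_threshold | no_peak_after_valley | short_trial | none


def filter_gsr(values_us: np.ndarray, sample_rate: float,
               low: float = 0.01, high: float = 5.0) -> np.ndarray:
    """Zero-phase 0.01-5 Hz conditioning of the conductance trace."""
    nyq = sample_rate / 2.0
    sos_hp = butter(1, low / nyq, btype="highpass", output="sos")
    sos_lp = butter(4, min(high, 0.99 * nyq) / nyq, btype="lowpass",
                    output="sos")
    return sosfiltfilt(sos_lp, sosfiltfilt(sos_hp, values_us))


def score_scr(time_s: np.ndarray, values_us: np.ndarray, onset_s: float,
              trial_id: int = 0) -> ScrScore:
    """Trough-to-peak score of one trial.

    Deterministic: ties in the minimum/maximum resolve to the earliest
    sample. Exclusions are reported as data, never raised.
    """
    t_ms = (np.asarray(time_s) - onset_s) * 1000.0
    v = np.asarray(values_us, dtype=float)
    if t_ms[-1] < TRIAL_SPAN_MS:
        return ScrScore(trial_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                        False, "short_trial")
    vmask = (t_ms >= VALLEY_WINDOW_MS[0]) & (t_ms <= VALLEY_WINDOW_MS[1])
    vi = np.flatnonzero(vmask)[np.argmin(v[vmask])]
    valley, valley_t = float(v[vi]), float(t_ms[vi])
    pmask = ((t_ms >= PEAK_WINDOW_MS[0]) & (t_ms <= PEAK_WINDOW_MS[1])
             & (t_ms > valley_t))
    if not pmask.any():
        return ScrScore(trial_id, valley, valley_t, np.nan, np.nan, np.nan,
                        False, "no_peak_after_valley")
    pi = np.flatnonzero(pmask)[np.argmax(v[pmask])]
    peak, peak_t = float(v[pi]), float(t_ms[pi])
    amp = peak - valley
    if amp < MIN_AMPLITUDE_US:
        return ScrScore(trial_id, valley, valley_t, peak, peak_t, amp,
                        False, "below_threshold")
    return ScrScore(trial_id, valley, valley_t, peak, peak_t, amp,
                    True, "none")


def score_scr_trace(scr, apply_filter: bool = True) -> pd.DataFrame:
    """Score every trial of a continuous trace (``synthetic_data.ScrTrace``)."""
    v = scr.values_us
    if apply_filter:
        v = filter_gsr(v, scr.sample_rate)
    rows = []
    for onset_s, trial_id, condition in scr.events:
        s = score_scr(scr.time_s, v, onset_s, trial_id)
        rows.append({"trial_id": trial_id, "condition": condition,
                     "valley_us": s.valley_us, "peak_us": s.peak_us,
                     "valley_latency_ms": s.valley_latency_ms,
                     "peak_latency_ms": s.peak_latency_ms,
                     "amplitude_us": s.amplitude_us, "valid": s.valid,
                     "exclusion_reason": s.exclusion_reason})
    return pd.DataFrame(rows)


def participant_scr_cells(scores: pd.DataFrame,
                          min_valid: int = 5) -> tuple[pd.DataFrame, bool]:
    """Per-condition mean amplitudes and the participant inclusion flag.

    The participant is included only if every condition holds at least
    ``min_valid`` valid trials; cell values average valid trials only.
    """
    cells = []
    included = True
    for cond, sub in scores.groupby("condition", sort=True):
        valid = sub[sub["valid"]]
        n = len(valid)
        if n < min_valid:
            included = False
        cells.append({"condition": cond, "n_valid": n,
                      "mean_amplitude_us": (valid["amplitude_us"].mean()
                                            if n else float("nan"))})
    return pd.DataFrame(cells), included


def hr_windows(beat_times_ms: np.ndarray, rr_ms: np.ndarray,
               onset_ms: float, windows=ATB_HR_WINDOWS,
               baseline_ms=HR_BASELINE_MS, grid_ms: float = 10.0,
               trial_id: int = 0) -> pd.DataFrame:
    """Baseline-corrected mean HR (bpm) per analysis window for one trial.

    Instantaneous HR (60000/RR) at the beat times is linearly
    interpolated to a uniform grid; each window mean has the baseline
    window mean subtracted. Windows not spanned by any beats yield NaN
    with a reason.
    """
    bt = np.asarray(beat_times_ms, dtype=float)
    hr = 60000.0 / np.asarray(rr_ms, dtype=float)

    def _mean(win):
        lo, hi = onset_ms + win[0], onset_ms + win[1]
        if bt[0] > hi or bt[-1] < lo:
            return np.nan
        grid = np.arange(lo, hi, grid_ms)
        return float(np.interp(grid, bt, hr).mean())

    base = _mean(baseline_ms)
    rows = []
    for name, win in windows.items():
        m = _mean(win)
        val = m - base if np.isfinite(m) and np.isfinite(base) else float("nan")
        rows.append({"trial_id": trial_id, "window": name, "mean_hr": val,
                     "reason": "" if np.isfinite(val) else "no beats in window"})
    return pd.DataFrame(rows)


def hr_table(rr, windows=ATB_HR_WINDOWS) -> pd.DataFrame:
    """Window means for every trial of an ``RrSeries``, with conditions."""
    frames = []
    for onset_ms, trial_id, condition in rr.events:
        df = hr_windows(rr.beat_times_ms, rr.rr_ms, onset_ms,
                        windows=windows, trial_id=trial_id)
        df["condition"] = condition
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
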