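"""Salivary hormone summaries: area under the curve.

Two trapezoidal summaries of a six-sample series: AUC with respect to
ground (AUCg) integrates the raw concentrations over all six timepoints;
AUC with respect to increment (AUCi) integrates from the second to the
sixth timepoint relative to the second (pre-stressor) sample, so it
captures change from baseline and is invariant to adding a constant to
the whole series.
"""

from __future__ import annotations

import numpy as np

from .synthetic_data import SALIVA_LABELS, SALIVA_TIMES_MIN


def _validate(times_min, values):
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need matching 1-d time and value arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if np.any(v < 0):
        raise ValueError("concentrations must be nonnegative")
    return t, v


def aucg(times_min, values) -> float:
    """Trapezoidal area over all samples (concentration x minutes)."""
    t, v = _validate(times_min, values)
    return float(np.trapezoid(v, t))


def auci(times_min, values, baseline_index: int = 1) -> float:
    """Trapezoidal area of points 2-6 above the second (pre-stressor)
    sample.

    ``baseline_index`` selects the reference sample (default the second,
    index 1, matching an increment computed from the second to the sixth
    timepoint; pass 0 to reference the first sample instead).
    """
    t, v = _validate(times_min, values)
    if not 0 <= baseline_index < len(t) - 1:
        raise ValueError("baseline index out of range")
    tt, vv = t[baseline_index:], v[baseline_index:]
    return float(np.trapezoid(vv, tt) - vv[0] * (tt[-1] - tt[0]))


def series_from_frame(frame, analyte: str):
    """Extract (times, values) for one analyte from a tidy saliva table
    with columns label/time_min/value, ordered by the canonical labels."""
    sub = frame[frame["analyte"] == analyte].set_index("label")
    times, values = [], []
    for lab, t in zip(SALIVA_LABELS, SALIVA_TIMES_MIN):
        if lab not in sub.index:
            raise ValueError(f"missing saliva sample {lab!r}")
        row = sub.loc[lab]
        times.append(float(row["time_min"]) if "time_min" in sub.columns else t)
        values.append(float(row["value"]))
    return np.asarray(times), np.asarray(values)
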