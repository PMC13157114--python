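"""Tagged-frequency ssVEP amplitudes and attentional bias scores.

Two faces flicker at distinct frequencies in opposite hemifields; the
steady-state response at each tag frequency indexes attention to that
face. Per trial, the Morlet envelope at each stimulus's own tag frequency
is averaged over a parieto-occipital electrode cluster and a time window,
trials are averaged within condition cells, and the attentional bias
score ABS = (A_high - A_low) / (A_high + A_low) contrasts the
higher-arousal against the lower-arousal face of the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochSet
from .spectral import amplitude_at, analysis_freqs, morlet_envelope

logger = logging.getLogger(__name__)

#: Parieto-occipital/occipital cluster carrying the flicker response.
SSVEP_CLUSTER = ("O1", "O2", "Oz", "PO7", "PO8", "P9", "P10")

#: Analysis windows (ms), half-open [t0, t1); four sub-windows plus the
#: global window.
WINDOWS = {
    "100-500": (100.0, 500.0),
    "500-1000": (500.0, 1000.0),
    "1000-2000": (1000.0, 2000.0),
    "2000-3000": (2000.0, 3000.0),
    "100-3000": (100.0, 3000.0),
}


@dataclass
class TfrAmplitude:
    """Morlet amplitude envelope, freqs x trials x channels x time (uV)."""

    freqs: np.ndarray
    time_ms: np.ndarray
    channel_labels: list[str]
    amplitude: np.ndarray
    edge_mask: np.ndarray  # freqs x time, True near epoch edges

    def freq_index(self, freq: float) -> int:
        idx = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[idx] - freq) > 1e-6:
            raise KeyError(f"{freq} Hz not in analysis set")
        return idx


def fft_amplitude(ep: EpochSet, window_ms=(0.0, 3000.0),
                  freqs=(12.0, 15.0), channels=None) -> pd.DataFrame:
    """Single-sided FFT amplitude at each tag frequency, per channel.

    Warns when the window does not hold an integer number of cycles at a
    tag frequency (leakage). Trials flagged as rejected are excluded; the
    spectrum is computed on the trial-averaged waveform.
    """
    t0, t1 = window_ms
    dt = 1000.0 / ep.sample_rate
    # half-open [t0, t1): the last epoch sample may sit dt before t1
    if t0 < ep.time_ms[0] or t1 > ep.time_ms[-1] + dt + 1e-9:
        raise ValueError("FFT window outside epoch")
    labels = list(channels) if channels is not None else list(ep.channel_labels)
    idx = ep.channel_indices(labels)
    mask = ep.time_mask(window_ms)
    keep = ~ep.rejected
    if not keep.any():
        raise ValueError("no unrejected trials")
    avg = ep.data[keep][:, idx][:, :, mask].mean(axis=0)
    rows = []
    for f in freqs:
        amps = amplitude_at(avg, ep.sample_rate, f)
        for lab, a in zip(labels, amps):
            rows.append({"freq": f, "channel": lab, "amplitude": float(a)})
    return pd.DataFrame(rows)


def morlet_amplitude(ep: EpochSet, freqs=None, n_cycles=None,
                     channels=None) -> TfrAmplitude:
    """Morlet amplitude envelope of each trial.

    Default frequency set: 10 log-spaced steps over 1-40 Hz with the two
    tag frequencies appended (the log grid does not land on them).
    Cycles default to freq/2; envelopes are normalized to unit
    stationary-sinusoid gain, with epoch-edge samples flagged.
    """
    if freqs is None:
        freqs = analysis_freqs()
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    labels = list(channels) if channels is not None else list(ep.channel_labels)
    idx = ep.channel_indices(labels)
    env, edge = morlet_envelope(ep.data[:, idx, :], ep.sample_rate, freqs,
                                n_cycles=n_cycles)
    return TfrAmplitude(freqs, ep.time_ms.copy(), labels, env, edge)


def tagged_amplitude(tfr: TfrAmplitude, freq: float, window_ms,
                     channels=SSVEP_CLUSTER,
                     trials: np.ndarray | None = None) -> np.ndarray:
    """Mean envelope at ``freq`` over the cluster and window, per trial."""
    fi = tfr.freq_index(freq)
    ci = np.array([tfr.channel_labels.index(c) for c in channels])
    t0, t1 = window_ms
    tm = (tfr.time_ms >= t0) & (tfr.time_ms < t1)
    amp = tfr.amplitude[fi][:, ci][:, :, tm].mean(axis=(1, 2))
    if trials is not None:
        amp = amp[trials]
    return amp


def abs_score(amp_high: float, amp_low: float) -> float:
    """Normalized attentional bias score (a - b) / (a + b) in [-1, 1].

    Undefined (NaN) when both amplitudes are zero; antisymmetric under
    swapping the two stimuli.
    """
    if amp_high < 0 or amp_low < 0:
        raise ValueError("amplitudes must be nonnegative")
    total = amp_high + amp_low
    if total == 0:
        logger.warning("ABS undefined: both amplitudes zero")
        return float("nan")
    return (amp_high - amp_low) / total


def abs_table(ep: EpochSet, participant: str = "", group: str = "",
              cluster=SSVEP_CLUSTER, windows=None,
              sum_both_tags: bool = False) -> pd.DataFrame:
    """Attentional-bias-score table: 5 windows x 3 combinations x 2
    hemifields per participant.

    Per trial the envelope at each stimulus's own tag frequency yields
    that stimulus's amplitude (``sum_both_tags=True`` instead sums the
    envelopes at both tags, an alternative reading kept behind a flag).
    Trial amplitudes are averaged within (combination x hemifield) cells
    before the ABS is formed; the hemifield key is the side showing the
    higher-arousal face. Rejected trials are excluded.
    """
    windows = windows or WINDOWS
    tags = sorted({c.freq_assignment["left"] for c in ep.conditions
                   if c.task == "atb"}
                  | {c.freq_assignment["right"] for c in ep.conditions
                     if c.task == "atb"})
    tfr = morlet_amplitude(ep, freqs=tags, channels=list(cluster))
    keep = ~ep.rejected
    per_window_amp = {}
    for wname, wspan in windows.items():
        per_window_amp[wname] = {f: tagged_amplitude(tfr, f, wspan, cluster)
                                 for f in tags}
    rows = []
    combos = sorted({c.combination for c in ep.conditions if c.task == "atb"})
    for comb in combos:
        for side in ("left", "right"):
            sel = np.array([
                keep[i] and c.combination == comb
                and c.side_of_higher_arousal == side
                for i, c in enumerate(ep.conditions)
            ])
            for wname in windows:
                if not sel.any():
                    rows.append({"participant": participant, "group": group,
                                 "combination": comb, "hemifield": side,
                                 "window": wname, "abs": float("nan"),
                                 "n_trials": 0})
                    continue
                highs, lows = [], []
                for i in np.flatnonzero(sel):
                    c = ep.conditions[i]
                    f_high = c.freq_assignment[side]
                    f_low = c.freq_assignment[
                        "right" if side == "left" else "left"]
                    if sum_both_tags:
                        a = sum(per_window_amp[wname][f][i] for f in tags)
                        b = a
                    else:
                        a = per_window_amp[wname][f_high][i]
                        b = per_window_amp[wname][f_low][i]
                    highs.append(a)
                    lows.append(b)
                rows.append({"participant": participant, "group": group,
                             "combination": comb, "hemifield": side,
                             "window": wname,
                             "abs": abs_score(float(np.mean(highs)),
                                              float(np.mean(lows))),
                             "n_trials": int(sel.sum())})
    return pd.DataFrame(rows)
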