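"""Frontal alpha event-related desynchronization (ERD).

Alpha-band (8-13 Hz) power at the frontopolar sites is estimated with the
package's Morlet engine (cycles = freq/2), log10-transformed per trial,
and contrasted between a post-stimulus window and the pre-stimulus
baseline. Negative values mean a stimulus-related power decrease
(desynchronization). For a pure multiplicative envelope gain g the
measure equals 2*log10(g), which anchors the recovery tests; the
200/2800 ms stimulus-window margins keep wavelet edge smearing of the
onset transition out of the averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EpochSet
from .spectral import morlet_envelope

logger = logging.getLogger(__name__)

FRONTAL_CLUSTER = ("Fp1", "Fp2", "Fpz")
ALPHA_BAND = (8.0, 13.0)
BASELINE_MS = (-200.0, 0.0)
STIM_MS = (200.0, 2800.0)

#: Epoch start for the spectral stage. The -200..0 ms baseline must clear
#: the wavelet support of the epoch edge (~400 ms at alpha frequencies
#: with cycles = freq/2), so ERD epochs begin earlier than the -200 ms
#: ERP epochs; all scoring windows are unchanged.
ERD_EPOCH_TMIN_MS = -700.0


@dataclass
class ErdResult:
    participant: str
    group: str
    erd_value: float  # mean log10 power, stimulus minus baseline
    time_resolved: np.ndarray  # trial-mean log10 power over the epoch
    time_ms: np.ndarray
    band: tuple
    channels: tuple
    reason: str = ""


def alpha_erd(ep: EpochSet, participant: str = "", group: str = "",
              channels=FRONTAL_CLUSTER, band=ALPHA_BAND, n_freqs: int = 6,
              baseline_ms=BASELINE_MS, stim_ms=STIM_MS,
              evoked: bool = False) -> ErdResult:
    """Alpha ERD for one participant's viewing epochs.

    Power is the squared Morlet envelope averaged over band frequencies
    and channels. By default single-trial (induced) power is
    log-transformed per trial and the baseline contrast averaged over
    trials; ``evoked=True`` instead averages the waveform over trials
    first. Zero power in the baseline of a trial makes the log
    undefined; such a case yields NaN with a recorded reason.
    """
    keep = ~ep.rejected
    if not keep.any():
        return ErdResult(participant, group, float("nan"),
                         np.array([]), np.array([]), band, tuple(channels),
                         reason="no unrejected trials")
    freqs = np.linspace(band[0], band[1], n_freqs)
    ci = ep.channel_indices(list(channels))
    data = ep.data[keep][:, ci, :]
    if evoked:
        data = data.mean(axis=0, keepdims=True)
    env, _ = morlet_envelope(data, ep.sample_rate, freqs)
    power = (env**2).mean(axis=(0, 2))  # trials x time
    bmask = (ep.time_ms >= baseline_ms[0]) & (ep.time_ms <= baseline_ms[1])
    smask = (ep.time_ms >= stim_ms[0]) & (ep.time_ms <= stim_ms[1])
    if power[:, bmask].min() <= 0 or power[:, smask].min() <= 0:
        logger.warning("zero alpha power: log undefined for %s", participant)
        return ErdResult(participant, group, float("nan"),
                         np.array([]), np.array([]), band, tuple(channels),
                         reason="zero power (log undefined)")
    logp = np.log10(power)
    per_trial = logp[:, smask].mean(axis=1) - logp[:, bmask].mean(axis=1)
    # time course relative to mean baseline, for plotting
    curve = logp.mean(axis=0) - logp[:, bmask].mean()
    return ErdResult(participant, group, float(per_trial.mean()),
                     curve, ep.time_ms.copy(), band, tuple(channels))
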