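"""Synthetic session generator with known ground truth.

Emulates the signal structure of a two-group (stress vs. control) acute
psychosocial-stress study: an attentional-bias task with two faces
flickering at 12 and 15 Hz in opposite hemifields, a passive face-viewing
task carrying ERP components and frontal alpha desynchronization, plus
skin-conductance traces, RR-interval series, six-point saliva series,
subjective stress ratings, and affective picture ratings.

Every quantity the downstream scorers estimate is injected here as an
explicit parameter, so recovery can be tested: tagged ssVEP amplitudes are
attention- and hemifield-weighted sinusoids with contralateral scalp
projection; ERPs are flat-topped (super-Gaussian) bumps with
expression-dependent amplitudes; alpha carries a multiplicative
post-stimulus envelope gain ``g`` (ERD); SCRs are bi-exponentials; heart
rate shows event-locked deceleration then acceleration.

Group effects are injected as parameter offsets: the stress group gets a
positive left-hemifield gain on the flicker amplitudes, globally
attenuated ERP amplitudes, and an ERD gain closer to 1 (weaker
desynchronization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    COMBINATIONS,
    EXPRESSIONS,
    HIGH_AROUSAL,
    LOW_AROUSAL,
    ContinuousRecording,
    TrialCondition,
    hemisphere_of,
)
from .montage import DEFAULT_CHANNELS

EPOCH_SPAN_MS = (-200.0, 3000.0)

SALIVA_LABELS = ("t-30", "t-pre", "t+00", "t+15", "t+30", "t+50")
#: Sample times in minutes relative to stressor onset. The pre-stressor
#: sample carries no numeric time in its label; -5 min is the default
#: mapping and can be overridden via SalivaParams.times_min.
SALIVA_TIMES_MIN = (-30.0, -5.0, 0.0, 15.0, 30.0, 50.0)

POSTERIOR_LEFT = ("O1", "PO7", "P7", "P9", "P3")
POSTERIOR_RIGHT = ("O2", "PO8", "P8", "P10", "P4")
POSTERIOR_MID = ("Oz", "POz", "Pz")


# --------------------------------------------------------------------------
# parameter blocks
# --------------------------------------------------------------------------

@dataclass
class SsvepParams:
    """Flicker-response model for the attentional-bias task."""

    base_amplitude_uv: float = 4.0
    #: Multiplicative attentional gain per expression (arousal ordering).
    attention_weights: dict = field(
        default_factory=lambda: {"angry": 1.25, "happy": 1.15, "neutral": 1.0}
    )
    #: Ipsilateral leakage of a lateralized stimulus onto same-side
    #: posterior channels (contralateral weight is 1).
    w_ipsi: float = 0.4
    #: Trial-to-trial lognormal amplitude jitter (sigma of log).
    trial_sigma: float = 0.2
    #: Between-participant SD of the hemifield bias parameter.
    subject_bias_sd: float = 0.25


@dataclass
class ErpComponent:
    name: str
    latency_ms: float
    halfwidth_ms: float
    base_amplitude_uv: float
    expression_offsets_uv: dict
    #: label -> projection weight
    channels: dict
    #: shape exponent of the flat-topped bump exp(-(|t-mu|/w)^order)
    order: int = 8


def _posterior_weights(labels, left_w, right_w):
    return {l: (left_w if hemisphere_of(l) == "left" else right_w) for l in labels}


def default_erp_components() -> list[ErpComponent]:
    """Template set: P1, N170, EPN, LPP with field-typical shapes.

    Latencies sit at the centers of the scoring windows (P1 80-120 ms,
    N170 130-200, EPN 240-300, LPP 400-1000); right-hemisphere weights
    exceed left to emulate the lateralization of face responses.
    """
    return [
        ErpComponent(
            "P1", 100.0, 35.0, 5.0,
            {"angry": 0.0, "happy": 0.0, "neutral": 0.0},
            _posterior_weights(("O1", "O2", "PO7", "PO8", "P9", "P10"), 0.85, 1.0),
        ),
        ErpComponent(
            "N170", 165.0, 45.0, -4.0,
            {"angry": -1.0, "happy": -0.2, "neutral": 0.0},
            _posterior_weights(("PO7", "PO8", "P9", "P10"), 0.75, 1.0),
        ),
        ErpComponent(
            "EPN", 270.0, 40.0, -2.0,
            {"angry": -0.8, "happy": -0.4, "neutral": 0.0},
            _posterior_weights(("P7", "P8", "PO7", "PO8", "P9", "P10"), 0.7, 1.0),
        ),
        ErpComponent(
            "LPP", 700.0, 320.0, 4.0,
            {"angry": 1.2, "happy": 0.8, "neutral": 0.0},
            {"Cz": 1.0, "CPz": 1.0, "Pz": 1.0, "POz": 1.0},
        ),
    ]


@dataclass
class ErpParams:
    components: list = field(default_factory=default_erp_components)
    #: Between-participant lognormal scale (sigma of log) on all amplitudes.
    subject_sigma: float = 0.25
    #: Trial-to-trial lognormal amplitude jitter.
    trial_sigma: float = 0.1


@dataclass
class AlphaParams:
    center_hz: float = 10.5
    #: Baseline alpha envelope amplitude at the frontal sites.
    envelope_uv: float = 10.0
    #: Post-stimulus envelope gain g in (0, 1]; ERD in log power is
    #: 2*log10(g).
    erd_gain: float = 0.5
    #: ERD onset after stimulus (ms) and ramp width (ms). The onset sits
    #: after t=0 so the pre-stimulus baseline window stays uncontaminated
    #: by wavelet smoothing of the transition.
    onset_ms: float = 150.0
    ramp_ms: float = 50.0
    frontal_weight: float = 1.0
    other_weight: float = 0.3


@dataclass
class NoiseParams:
    exponent: float = 1.0
    sd_uv: float = 5.0


@dataclass
class ScrParams:
    rise_s: float = 0.75
    decay_s: float = 6.0
    latency_s: float = 2.0
    #: Mean trough-to-peak amplitude (uS) per condition.
    amplitudes_us: dict = field(
        default_factory=lambda: {
            "angry-neutral": 0.25, "angry-happy": 0.30, "happy-neutral": 0.35,
            "angry": 0.30, "happy": 0.28, "neutral": 0.22,
        }
    )
    trial_sigma: float = 0.6
    response_prob: float = 0.85
    tonic_us: float = 2.0
    noise_sd_us: float = 0.003
    sample_rate: float = 32.0


@dataclass
class RrParams:
    baseline_ms: float = 850.0
    decel_depth_ms: float = 50.0
    accel_depth_ms: float = 30.0
    noise_ms: float = 8.0


@dataclass
class SalivaParams:
    labels: tuple = SALIVA_LABELS
    times_min: tuple = SALIVA_TIMES_MIN
    cortisol_nmol_l: dict = field(
        default_factory=lambda: {
            "stress": (8.0, 7.2, 6.6, 6.0, 5.4, 4.8),
            "control": (8.0, 7.2, 6.6, 6.0, 5.4, 4.8),
        }
    )
    saa_u_ml: dict = field(
        default_factory=lambda: {
            "stress": (100.0, 102.0, 140.0, 112.0, 104.0, 100.0),
            "control": (100.0, 102.0, 140.0, 112.0, 104.0, 100.0),
        }
    )
    #: Subjective stress (visual-analog scale, 0-100): the stress group
    #: peaks right after the stressor, controls stay flat.
    vas: dict = field(
        default_factory=lambda: {
            "stress": (30.0, 33.0, 58.0, 40.0, 33.0, 30.0),
            "control": (30.0, 32.0, 33.0, 30.0, 28.0, 27.0),
        }
    )
    cortisol_noise: float = 1.2
    saa_noise: float = 20.0
    vas_noise: float = 8.0
    subject_sd_frac: float = 0.15


@dataclass
class RatingsParams:
    """Affective picture ratings on a 0-1 scale, [group][expression] ->
    (mean, sd)."""

    arousal: dict = field(
        default_factory=lambda: {
            "stress": {"angry": (0.58, 0.14), "happy": (0.52, 0.17),
                       "neutral": (0.37, 0.14)},
            "control": {"angry": (0.55, 0.14), "happy": (0.51, 0.13),
                        "neutral": (0.42, 0.11)},
        }
    )
    valence: dict = field(
        default_factory=lambda: {
            "stress": {"angry": (0.21, 0.086), "happy": (0.79, 0.080),
                       "neutral": (0.43, 0.057)},
            "control": {"angry": (0.26, 0.095), "happy": (0.75, 0.10),
                        "neutral": (0.43, 0.050)},
        }
    )


@dataclass
class SimulationConfig:
    """Full generative configuration; defaults mirror the study design.

    40 participants per group; ATB trials of 3000 ms with 4500-5500 ms
    inter-trial intervals, 96 trials per emotional combination
    counterbalanced over hemifield and flicker-frequency assignment;
    96 passive-viewing trials (32 per expression); EEG sampled at 512 Hz
    with 12 and 15 Hz tag frequencies.
    """

    n_participants_per_group: int = 40
    n_trials_atb: int = 96          # per combination, divisible by 4
    n_trials_viewing: int = 32      # per expression
    sample_rate: float = 512.0
    tag_freqs: tuple = (12.0, 15.0)
    channels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    iti_atb_ms: tuple = (4500.0, 5500.0)
    #: Viewing-task inter-trial interval (rating period between stimuli);
    #: not constrained by the study design, exposed as a parameter.
    iti_viewing_ms: tuple = (4500.0, 5500.0)
    ssvep: SsvepParams = field(default_factory=SsvepParams)
    erp: ErpParams = field(default_factory=ErpParams)
    alpha: AlphaParams = field(default_factory=AlphaParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    scr: ScrParams = field(default_factory=ScrParams)
    rr: RrParams = field(default_factory=RrParams)
    saliva: SalivaParams = field(default_factory=SalivaParams)
    ratings: RatingsParams = field(default_factory=RatingsParams)
    #: Group-effect parameters (stress vs. control offsets).
    hemifield_bias: dict = field(
        default_factory=lambda: {"stress": 0.2, "control": 0.0}
    )
    erp_attenuation: dict = field(
        default_factory=lambda: {"stress": 0.8, "control": 1.0}
    )
    erd_gain: dict = field(
        default_factory=lambda: {"stress": 0.7, "control": 0.5}
    )
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sample_rate / 2.0
        f1, f2 = self.tag_freqs
        if f1 == f2:
            raise ValueError("tag frequencies must be distinct")
        if not (0 < f1 < nyq and 0 < f2 < nyq):
            raise ValueError("tag frequencies must lie below Nyquist")
        if self.n_trials_atb % 4 != 0:
            raise ValueError(
                "n_trials_atb must be divisible by 4 for exact "
                "hemifield x frequency counterbalancing"
            )
        min_spacing = 3000.0 + min(self.iti_atb_ms)
        span = EPOCH_SPAN_MS[1] - EPOCH_SPAN_MS[0]
        if min_spacing < span:
            raise ValueError("trial spacing shorter than the epoch span")
        if not (0.0 < self.alpha.erd_gain <= 1.0):
            raise ValueError("erd_gain must lie in (0, 1]")
        for g, gain in self.erd_gain.items():
            if not (0.0 < gain <= 1.0):
                raise ValueError(f"erd_gain[{g}] must lie in (0, 1]")
        for w in self.ssvep.attention_weights.values():
            if w < 0:
                raise ValueError("attention weights must be nonnegative")
        if not (0.0 <= self.ssvep.w_ipsi < 1.0):
            raise ValueError("w_ipsi must lie in [0, 1)")
        if self.noise.sd_uv < 0 or self.alpha.envelope_uv < 0:
            raise ValueError("amplitudes and SDs must be nonnegative")
        if self.scr.decay_s <= self.scr.rise_s:
            raise ValueError("SCR decay must exceed rise time constant")


# --------------------------------------------------------------------------
# elemental waveforms
# --------------------------------------------------------------------------

def ssvep_signal(t_s: np.ndarray, freq: float, amplitude: float,
                 phase: float = 0.0, sample_rate: float | None = None) -> np.ndarray:
    """Pure flicker-following sinusoid, amplitude in uV."""
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if sample_rate is not None and freq >= sample_rate / 2:
        raise ValueError("flicker frequency at or above Nyquist")
    return amplitude * np.sin(2.0 * np.pi * freq * np.asarray(t_s) + phase)


def hemifield_weights(side: str, labels, w_ipsi: float = 0.4) -> np.ndarray:
    """Scalp projection of a lateralized stimulus.

    Contralateral posterior channels get weight 1, ipsilateral posterior
    channels ``w_ipsi``, posterior midline the average, everything else 0.
    """
    contra = POSTERIOR_RIGHT if side == "left" else POSTERIOR_LEFT
    ipsi = POSTERIOR_LEFT if side == "left" else POSTERIOR_RIGHT
    w = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab in contra:
            w[i] = 1.0
        elif lab in ipsi:
            w[i] = w_ipsi
        elif lab in POSTERIOR_MID:
            w[i] = (1.0 + w_ipsi) / 2.0
    return w


def _bump(t_ms: np.ndarray, latency: float, halfwidth: float, order: int) -> np.ndarray:
    # flat-topped bump: ~1 across most of the scoring window, fast falloff
    return np.exp(-np.abs((t_ms - latency) / halfwidth) ** order)


def erp_template(erp_params: ErpParams, expression: str, time_ms: np.ndarray,
                 labels, amplitude_scale: float = 1.0) -> np.ndarray:
    """Noiseless ERP template, channels x time, in uV.

    Sum over components of flat-topped bumps scaled by the component's
    base amplitude plus its per-expression offset, projected through the
    per-channel weights; ``amplitude_scale`` applies a global gain
    (subject scale and/or group attenuation).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    out = np.zeros((len(labels), len(time_ms)))
    for comp in erp_params.components:
        if comp.halfwidth_ms <= 0:
            raise ValueError("component halfwidth must be positive")
        amp = comp.base_amplitude_uv + comp.expression_offsets_uv.get(expression, 0.0)
        shape = _bump(time_ms, comp.latency_ms, comp.halfwidth_ms, comp.order)
        for i, lab in enumerate(labels):
            w = comp.channels.get(lab, 0.0)
            if w:
                out[i] += amplitude_scale * amp * w * shape
    return out


def scr_trace(t_s: np.ndarray, onset_s: float, amplitude_us: float,
              rise_s: float = 0.75, decay_s: float = 6.0) -> np.ndarray:
    """Bi-exponential skin-conductance response, peak-normalized.

    r(t) = a * (exp(-(t-t0)/decay) - exp(-(t-t0)/rise)) for t >= t0,
    scaled so the maximum equals ``amplitude_us``; zero before onset.
    """
    if decay_s <= rise_s or rise_s <= 0:
        raise ValueError("need decay_s > rise_s > 0")
    if amplitude_us < 0:
        raise ValueError("amplitude must be nonnegative")
    t = np.asarray(t_s, dtype=float)
    dt = t - onset_s
    shape = np.where(dt >= 0, np.exp(-np.clip(dt, 0, None) / decay_s)
                     - np.exp(-np.clip(dt, 0, None) / rise_s), 0.0)
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return amplitude_us * shape / peak


def one_over_f_noise(n_samples: int, sd_uv: float, exponent: float,
                     sample_rate: float, rng: np.random.Generator,
                     shape=()) -> np.ndarray:
    """Spectrally shaped noise with power ~ 1/f**exponent, given SD.

    The shaping is flat below 1 Hz to keep the spectrum integrable.
    """
    if sd_uv == 0:
        return np.zeros(shape + (n_samples,))
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = np.ones_like(freqs)
    nz = freqs > 1.0
    scale[nz] = (freqs[nz]) ** (-exponent / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n_samples, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd_uv * shaped / std


# --------------------------------------------------------------------------
# condition tables
# --------------------------------------------------------------------------

def atb_condition_cells(config: SimulationConfig) -> list[tuple]:
    """Exactly counterbalanced (combination, side, frequency-assignment)
    cell list, one entry per trial (unshuffled)."""
    f1, f2 = config.tag_freqs
    assignments = ({"left": f1, "right": f2}, {"left": f2, "right": f1})
    reps = config.n_trials_atb // 4
    cells = []
    for comb in COMBINATIONS:
        for side in ("left", "right"):
            for fa in assignments:
                cells.extend([(comb, side, dict(fa))] * reps)
    return cells


# --------------------------------------------------------------------------
# session assembly
# --------------------------------------------------------------------------

@dataclass
class ScrTrace:
    time_s: np.ndarray
    values_us: np.ndarray
    sample_rate: float
    #: (onset_s, trial_id, condition) per trial
    events: list


@dataclass
class RrSeries:
    beat_times_ms: np.ndarray
    rr_ms: np.ndarray
    #: (onset_ms, trial_id, condition) per trial
    events: list


@dataclass
class Session:
    participant: str
    group: str
    atb: ContinuousRecording
    atb_conditions: list
    viewing: ContinuousRecording
    viewing_conditions: list
    scr_atb: ScrTrace
    scr_viewing: ScrTrace
    rr_atb: RrSeries
    rr_viewing: RrSeries
    saliva: pd.DataFrame
    ratings: pd.DataFrame
    ground_truth: dict


def _trial_onsets(n_trials: int, sample_rate: float, iti_ms, rng,
                  lead_s: float = 2.0, trial_s: float = 3.0,
                  tail_s: float = 9.0):
    onsets = []
    t = lead_s
    for _ in range(n_trials):
        onsets.append(int(round(t * sample_rate)))
        iti = rng.uniform(*iti_ms) / 1000.0
        t += trial_s + iti
    n_samples = int(round((t + tail_s) * sample_rate))
    return np.array(onsets), n_samples


def _alpha_signal(n_samples, onsets, sample_rate, alpha: AlphaParams,
                  erd_gain, labels, rng):
    """Continuous alpha with a multiplicative envelope dip after each
    stimulus; dip onset/offset ramps are Gaussian-CDF shaped."""
    from scipy.stats import norm

    t = np.arange(n_samples) / sample_rate
    envelope = np.ones(n_samples)
    onset_s = alpha.onset_ms / 1000.0
    ramp_s = alpha.ramp_ms / 1000.0
    for onset in onsets:
        t0 = onset / sample_rate
        dip = norm.cdf((t - t0 - onset_s) / ramp_s) * (
            1.0 - norm.cdf((t - t0 - 3.0) / (2 * ramp_s)))
        envelope *= 1.0 - (1.0 - erd_gain) * dip
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * alpha.center_hz * t + phase)
    sig = alpha.envelope_uv * envelope * carrier
    weights = np.array([
        alpha.frontal_weight if lab in ("Fp1", "Fpz", "Fp2") else alpha.other_weight
        for lab in labels
    ])
    return weights[:, None] * sig[None, :]


def _simulate_atb_eeg(config, group, rng):
    fs = config.sample_rate
    p = config.ssvep
    cells = atb_condition_cells(config)
    order = rng.permutation(len(cells))
    onsets, n_samples = _trial_onsets(len(cells), fs, config.iti_atb_ms, rng)
    labels = config.channels
    beta = rng.normal(config.hemifield_bias[group], p.subject_bias_sd)
    data = one_over_f_noise(n_samples, config.noise.sd_uv, config.noise.exponent,
                            fs, rng, shape=(len(labels),))
    conditions = []
    truth_amps = []
    trial_samples = int(round(3.0 * fs))
    w_by_side = {s: hemifield_weights(s, labels, p.w_ipsi) for s in ("left", "right")}
    for trial_id, (cell_idx, onset) in enumerate(zip(order, onsets)):
        comb, side_high, fa = cells[cell_idx]
        cond = TrialCondition(task="atb", trial_id=trial_id,
                              onset_sample=int(onset), combination=comb,
                              side_of_higher_arousal=side_high,
                              freq_assignment=fa)
        conditions.append(cond)
        t_rel = np.arange(trial_samples) / fs
        side_expr = {side_high: HIGH_AROUSAL[comb],
                     ("right" if side_high == "left" else "left"): LOW_AROUSAL[comb]}
        amps = {}
        for side in ("left", "right"):
            gain = (1.0 + beta) if side == "left" else (1.0 - beta)
            gain = max(gain, 0.0)
            amp = (p.base_amplitude_uv * p.attention_weights[side_expr[side]]
                   * gain)
            if p.trial_sigma > 0:
                amp *= np.exp(rng.normal(0.0, p.trial_sigma))
            phase = rng.uniform(0, 2 * np.pi)
            wave = ssvep_signal(t_rel, fa[side], amp, phase, sample_rate=fs)
            sl = slice(onset, onset + trial_samples)
            data[:, sl] += w_by_side[side][:, None] * wave[None, :]
            amps[side] = amp
        truth_amps.append(amps)
    rec = ContinuousRecording(labels, fs, data,
                              [(int(o), i) for i, o in enumerate(onsets)])
    truth = {"hemifield_bias": beta, "trial_amplitudes": truth_amps}
    return rec, conditions, truth


def _simulate_viewing_eeg(config, group, rng):
    fs = config.sample_rate
    labels = config.channels
    exprs = list(EXPRESSIONS) * config.n_trials_viewing
    order = rng.permutation(len(exprs))
    onsets, n_samples = _trial_onsets(len(exprs), fs, config.iti_viewing_ms, rng)
    subject_scale = (config.erp_attenuation[group]
                     * np.exp(rng.normal(0.0, config.erp.subject_sigma)))
    erd_gain = config.erd_gain[group]
    data = one_over_f_noise(n_samples, config.noise.sd_uv, config.noise.exponent,
                            fs, rng, shape=(len(labels),))
    data += _alpha_signal(n_samples, onsets, fs, config.alpha, erd_gain,
                          labels, rng)
    span = EPOCH_SPAN_MS
    n_t = int(round((span[1] - span[0]) / 1000.0 * fs)) + 1
    t_ms = span[0] + np.arange(n_t) / fs * 1000.0
    conditions = []
    for trial_id, (idx, onset) in enumerate(zip(order, onsets)):
        expr = exprs[idx]
        conditions.append(TrialCondition(task="viewing", trial_id=trial_id,
                                         onset_sample=int(onset),
                                         expression=expr))
        scale = subject_scale
        if config.erp.trial_sigma > 0:
            scale = scale * np.exp(rng.normal(0.0, config.erp.trial_sigma))
        template = erp_template(config.erp, expr, t_ms, labels, scale)
        start = onset + int(round(span[0] / 1000.0 * fs))
        data[:, start:start + n_t] += template
    rec = ContinuousRecording(labels, fs, data,
                              [(int(o), i) for i, o in enumerate(onsets)])
    truth = {"subject_scale": subject_scale, "erd_gain": erd_gain}
    return rec, conditions, truth


def _simulate_scr(conditions, sample_rate_eeg, config, rng):
    p = config.scr
    last_onset_s = max(c.onset_sample for c in conditions) / sample_rate_eeg
    dur = last_onset_s + 12.0
    fs = p.sample_rate
    t = np.arange(int(round(dur * fs))) / fs
    vals = np.full_like(t, p.tonic_us)
    if p.noise_sd_us > 0:
        vals = vals + rng.normal(0.0, p.noise_sd_us, size=t.shape)
    events = []
    for c in conditions:
        onset_s = c.onset_sample / sample_rate_eeg
        cond = c.combination if c.task == "atb" else c.expression
        if rng.uniform() < p.response_prob:
            amp = p.amplitudes_us[cond] * np.exp(rng.normal(0.0, p.trial_sigma))
        else:
            amp = 0.0
        if amp > 0:
            vals += scr_trace(t, onset_s + p.latency_s, amp, p.rise_s, p.decay_s)
        events.append((onset_s, c.trial_id, cond))
    return ScrTrace(t, vals, fs, events)


def _rr_profile(tau_s, decel, accel):
    """Event-locked RR modulation (ms): lengthening 0-1 s (HR
    deceleration), shortening 1-3 s (acceleration)."""
    tau = np.asarray(tau_s, dtype=float)
    out = np.zeros_like(tau)
    m = (tau >= 0) & (tau < 1.0)
    out[m] = decel * np.sin(np.pi * tau[m])
    m = (tau >= 1.0) & (tau < 3.0)
    out[m] = -accel * np.sin(np.pi * (tau[m] - 1.0) / 2.0)
    return out


def _simulate_rr(conditions, sample_rate_eeg, config, rng):
    p = config.rr
    onsets_s = np.array([c.onset_sample / sample_rate_eeg for c in conditions])
    conds = [c.combination if c.task == "atb" else c.expression
             for c in conditions]
    dur = onsets_s.max() + 12.0
    beats = []
    rrs = []
    t = 0.0
    while t < dur:
        dt = t - onsets_s
        recent = dt[(dt >= 0) & (dt < 3.0)]
        mod = _rr_profile(recent, p.decel_depth_ms, p.accel_depth_ms).sum()
        rr = p.baseline_ms + mod + rng.normal(0.0, p.noise_ms)
        beats.append(t * 1000.0)
        rrs.append(rr)
        t += rr / 1000.0
    events = [(o * 1000.0, c.trial_id, cond)
              for o, c, cond in zip(onsets_s, conditions, conds)]
    return RrSeries(np.array(beats), np.array(rrs), events)


def _simulate_saliva(config, group, rng):
    p = config.saliva
    rows = []
    series = {"cortisol": (p.cortisol_nmol_l[group], p.cortisol_noise),
              "saa": (p.saa_u_ml[group], p.saa_noise),
              "vas": (p.vas[group], p.vas_noise)}
    for analyte, (means, noise) in series.items():
        intercept = rng.normal(0.0, p.subject_sd_frac * np.mean(means))
        for lab, t_min, mu in zip(p.labels, p.times_min, means):
            val = max(mu + intercept + rng.normal(0.0, noise), 0.0)
            rows.append({"analyte": analyte, "label": lab,
                         "time_min": t_min, "value": val})
    return pd.DataFrame(rows)


def _simulate_ratings(config, group, rng):
    rows = []
    for expr in EXPRESSIONS:
        a_mu, a_sd = config.ratings.arousal[group][expr]
        v_mu, v_sd = config.ratings.valence[group][expr]
        rows.append({
            "expression": expr,
            "arousal": float(np.clip(rng.normal(a_mu, a_sd), 0.0, 1.0)),
            "valence": float(np.clip(rng.normal(v_mu, v_sd), 0.0, 1.0)),
        })
    return pd.DataFrame(rows)


def participant_rng(config: SimulationConfig, group: str, index: int):
    gcode = 0 if group == "stress" else 1
    return np.random.default_rng([config.seed, gcode, index])


def generate_session(config: SimulationConfig, group: str,
                     participant_index: int = 0) -> Session:
    """Generate one participant's full synthetic session.

    Deterministic given (config.seed, group, participant_index). Ground
    truth (hemifield bias, subject ERP scale, ERD gain, per-trial flicker
    amplitudes) travels with the output for recovery tests.
    """
    if group not in ("stress", "control"):
        raise ValueError("group must be 'stress' or 'control'")
    config.validate()
    rng = participant_rng(config, group, participant_index)
    atb_rec, atb_cond, atb_truth = _simulate_atb_eeg(config, group, rng)
    view_rec, view_cond, view_truth = _simulate_viewing_eeg(config, group, rng)
    scr_atb = _simulate_scr(atb_cond, config.sample_rate, config, rng)
    scr_view = _simulate_scr(view_cond, config.sample_rate, config, rng)
    rr_atb = _simulate_rr(atb_cond, config.sample_rate, config, rng)
    rr_view = _simulate_rr(view_cond, config.sample_rate, config, rng)
    saliva = _simulate_saliva(config, group, rng)
    ratings = _simulate_ratings(config, group, rng)
    pid = f"{group[0]}{participant_index:03d}"
    truth = {"atb": atb_truth, "viewing": view_truth,
             "config": asdict(config)}
    return Session(pid, group, atb_rec, atb_cond, view_rec, view_cond,
                   scr_atb, scr_view, rr_atb, rr_view, saliva, ratings, truth)


# --------------------------------------------------------------------------
# amplitude-level experiment samplers
# --------------------------------------------------------------------------
# These sample condition-cell summary measures directly from the same
# parametric model that drives the raw-signal generator (hemifield bias
# beta_i ~ N(beta_group, sd), attention weights, multiplicative cell
# noise), skipping waveform synthesis. They make many-experiment power
# studies tractable; a dedicated test checks that the raw-EEG route
# yields the same cell structure.

def sample_bias_experiment(config: SimulationConfig, rng,
                           cell_sigma: float = 0.35) -> pd.DataFrame:
    """Per-participant attentional-bias scores for one simulated
    experiment (global window), long format."""
    p = config.ssvep
    rows = []
    for group in ("stress", "control"):
        beta_mu = config.hemifield_bias[group]
        for i in range(config.n_participants_per_group):
            beta = rng.normal(beta_mu, p.subject_bias_sd)
            pid = f"{group[0]}{i:03d}"
            for comb in COMBINATIONS:
                w_hi = p.attention_weights[HIGH_AROUSAL[comb]]
                w_lo = p.attention_weights[LOW_AROUSAL[comb]]
                for side in ("left", "right"):
                    g_hi = max(1.0 + beta if side == "left" else 1.0 - beta, 0.0)
                    g_lo = max(1.0 - beta if side == "left" else 1.0 + beta, 0.0)
                    a = (p.base_amplitude_uv * w_hi * g_hi
                         * np.exp(rng.normal(0.0, cell_sigma)))
                    b = (p.base_amplitude_uv * w_lo * g_lo
                         * np.exp(rng.normal(0.0, cell_sigma)))
                    abs_score = (a - b) / (a + b)
                    rows.append({"participant": pid, "group": group,
                                 "combination": comb, "hemifield": side,
                                 "abs": abs_score})
    return pd.DataFrame(rows)


def sample_erp_experiment(config: SimulationConfig, rng,
                          component: str = "LPP",
                          cell_sigma: float = 0.5) -> pd.DataFrame:
    """Per-participant mean component amplitudes for one simulated
    experiment, long format (group x expression)."""
    comp = next(c for c in config.erp.components if c.name == component)
    rows = []
    for group in ("stress", "control"):
        atten = config.erp_attenuation[group]
        for i in range(config.n_participants_per_group):
            scale = atten * np.exp(rng.normal(0.0, config.erp.subject_sigma))
            pid = f"{group[0]}{i:03d}"
            for expr in EXPRESSIONS:
                amp = (comp.base_amplitude_uv
                       + comp.expression_offsets_uv.get(expr, 0.0))
                val = scale * amp + rng.normal(0.0, cell_sigma)
                rows.append({"participant": pid, "group": group,
                             "expression": expr, "amplitude": val})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------

def write_session(session: Session, outdir) -> None:
    """Write a session to ``outdir`` as plain-text artifacts.

    EEG goes to .npy arrays with sidecar TSVs for channels and events;
    SCR/RR/saliva/ratings are two-or-more-column TSVs.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    pid = session.participant

    def _events_frame(conditions):
        rows = []
        for c in conditions:
            rows.append({
                "onset_sample": c.onset_sample, "trial_id": c.trial_id,
                "task": c.task, "combination": c.combination or "",
                "side_of_higher_arousal": c.side_of_higher_arousal or "",
                "freq_left": (c.freq_assignment or {}).get("left", ""),
                "freq_right": (c.freq_assignment or {}).get("right", ""),
                "expression": c.expression or "",
            })
        return pd.DataFrame(rows)

    for task, rec, conds in (("atb", session.atb, session.atb_conditions),
                             ("viewing", session.viewing,
                              session.viewing_conditions)):
        np.save(os.path.join(outdir, f"{pid}_{task}_eeg.npy"), rec.data)
        pd.DataFrame({"channel": rec.channel_labels}).to_csv(
            os.path.join(outdir, f"{pid}_{task}_channels.tsv"),
            sep="\t", index=False)
        _events_frame(conds).to_csv(
            os.path.join(outdir, f"{pid}_{task}_events.tsv"),
            sep="\t", index=False)
    for task, scr in (("atb", session.scr_atb), ("viewing", session.scr_viewing)):
        pd.DataFrame({"time_s": scr.time_s, "microsiemens": scr.values_us}
                     ).to_csv(os.path.join(outdir, f"{pid}_{task}_scr.tsv"),
                              sep="\t", index=False)
    for task, rr in (("atb", session.rr_atb), ("viewing", session.rr_viewing)):
        pd.DataFrame({"beat_time_ms": rr.beat_times_ms, "rr_ms": rr.rr_ms}
                     ).to_csv(os.path.join(outdir, f"{pid}_{task}_rr.tsv"),
                              sep="\t", index=False)
    session.saliva.to_csv(os.path.join(outdir, f"{pid}_saliva.tsv"),
                          sep="\t", index=False)
    session.ratings.to_csv(os.path.join(outdir, f"{pid}_ratings.tsv"),
                           sep="\t", index=False)
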