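# Methods

This note documents the generative model, the scoring conventions, the
numerical choices and their rationale, and what the synthetic-data tests
do and do not establish about real recordings.

## The simulated experiment

The generator emulates a two-group acute-stress study. Each simulated
participant contributes:

- an **attentional-bias (ATB) task**: pairs of emotional faces
  (angry–neutral, angry–happy, happy–neutral) flickering at 12 and 15 Hz
  in opposite hemifields, 3000 ms trials with 4500–5500 ms inter-trial
  intervals, combination × hemifield × frequency assignment exactly
  counterbalanced (trial counts per combination must be divisible by 4);
- a **passive-viewing task**: single angry/happy/neutral faces, ERP
  templates plus continuous alpha with post-stimulus desynchronization;
- continuous **skin conductance** and **RR-interval** series with
  event-locked responses;
- six-point **saliva** series (cortisol, alpha-amylase, subjective
  stress) and affective **ratings**.

EEG is synthesized at 512 Hz on a 27-channel schematic 10-20 montage
with 1/f-shaped background noise (exponent 1, SD 5 µV). Identical seed
and configuration give bit-identical output; the per-participant stream
is derived from (seed, group, participant index).

### Flicker responses

Each stimulus contributes a pure sinusoid at its tag frequency whose
amplitude is `base × attention_weight(expression) × hemifield gain`,
projected with weight 1 to contralateral posterior channels, `w_ipsi`
(default 0.4) ipsilaterally, and the average of the two on the posterior
midline. Attention weights default to angry 1.25, happy 1.15, neutral
1.0 — an arousal ordering at plausible magnitude; the stress group gets
a hemifield gain (1 + β) on left-field stimuli and (1 − β) on the right,
with β drawn per subject from N(0.2, 0.25²) (controls: mean 0).

The **base flicker amplitude defaults to 4 µV**. The Morlet envelope of
the 1/f background adds a positive amplitude floor (~1.3 µV per channel
at 12 Hz for 5 µV noise) to both amplitudes of a pair, which shrinks
measured bias scores toward zero; 4 µV keeps the measured ABS
distribution on the scale such studies report. This floor — and a
related crosstalk between the 12 and 15 Hz wavelets, whose ~2 Hz
spectral width spans part of the 3 Hz tag separation — means
envelope-based bias scores are conservative: ratios injected at 1.5 are
read back around 1.35–1.45. The leakage-free FFT route over the full
3 s window (where both tags fall on exact bins) recovers injected
amplitudes without bias and anchors the cross-route tests.

### ERP templates

Components are flat-topped super-Gaussian bumps
`A·exp(−(|t−μ|/w)^8)` rather than plain Gaussians: the scorer is a
window mean, and a Gaussian wide enough to fill its scoring window to
within a few percent would overlap the neighboring component, whereas
the order-8 bump is ≈1 across the window and ≈0 outside it. Defaults:
P1 (+5 µV, 100 ms, w=35), N170 (−4 µV with −1 µV angry offset, 165 ms,
w=45), EPN (−2 µV, 270 ms, w=40), LPP (+4 µV with +1.2/+0.8 µV
angry/happy offsets, 700 ms, w=320). Lateral components project with
right-hemisphere weight 1.0 vs. left 0.7–0.85 to emulate the
right-lateralization of face responses; recovery tests score the
right-hemisphere (unit-weight) cells so injected amplitudes come back
unscaled. The stress group's amplitudes are globally attenuated
(factor 0.8); subjects carry a lognormal scale (σ = 0.25).

### Alpha and ERD

Alpha is a 10.5 Hz sinusoid (envelope 10 µV frontally, 0.3 weight
elsewhere) whose envelope drops to `g × baseline` after each stimulus.
The dip onset is centered 150 ms post-stimulus with a 50 ms ramp: placed
after t = 0 so that wavelet smoothing of the transition does not reach
into the −200–0 ms baseline window, and fast enough that the 200 ms
margin of the 200–2800 ms stimulus window clears the ramp. ERD gains
default to 0.5 (control) and 0.7 (stress): the stress group
desynchronizes less.

### Autonomic and endocrine signals

SCRs are bi-exponentials `a(e^{−t/τd} − e^{−t/τr})`, peak-normalized,
with rise 0.75 s, decay 6 s, onset latency 2 s and condition-specific
mean amplitudes (happy–neutral pairs largest); 15% of trials are
non-responses and per-trial amplitudes are lognormal. RR series are
generated beat by beat: baseline 850 ms with +50 ms lengthening over
0–1 s (deceleration) and −30 ms shortening over 1–3 s (acceleration).
Saliva trajectories decline over the session (cortisol), peak right
after the stressor (alpha-amylase), and carry a stress-group-specific
subjective-stress peak at t+00; sampling times map the labeled points
to (−30, −5, 0, +15, +30, +50) minutes, with the pre-stressor time
configurable since only its label is fixed.

## Scoring conventions

- **Preprocessing order**: bandpass → notch → interpolation → (artifact
  hook) → epoch → average reference → baseline → rejection; the epoch
  history records the applied order. Component-based artifact removal
  needs human/classifier judgment and the synthetic data carries no such
  artifacts, so the hook is a pass-through accepting a user-supplied
  remover.
- **Bandpass** (0.01–40 Hz) is a zero-phase spectral filter with the
  Butterworth amplitude response (order 4 on both edges), applied after
  linear detrending. A forward–backward IIR at a 0.01 Hz corner has a
  ~16 s settling transient that corrupts passband amplitudes on any
  finite recording; the spectral form keeps the passband gain exact and
  still attenuates ≥ 20 dB one octave beyond the edges. The 50 Hz notch
  stays a time-domain zero-phase IIR.
- **Epochs** span −200–3000 ms with `round(Δt·fs) + 1` samples (1639 at
  512 Hz, endpoint-inclusive convention). Events too close to a
  recording edge are flagged, not dropped. Amplitude rejection reads
  "exceeding 150 µV" as |v| > 150 µV on any channel at any sample.
- **Bad-channel interpolation** is inverse-distance averaging over the
  four nearest neighbors on a schematic 2-D 10-20 layout; without
  electrode digitization a spherical-spline model would pretend to
  geometry the data do not have.
- **Morlet envelopes** use cycles = f/2 (constant ~80 ms temporal width
  across the band) and are normalized so a stationary unit sinusoid
  reads 1.0. Epoch edges are handled by zero-padding plus division by
  the local Gaussian coverage, which makes the stationary-tone gain
  exact at every sample (reflection padding was tested and is worse);
  samples within 3σ of an edge are still flagged. The analysis grid is
  10 log-spaced frequencies over 1–40 Hz with the two tag frequencies
  appended, since the log grid does not land on them.
- **Bias scores** key each stimulus by its own tag frequency; the
  alternative reading that sums envelopes across both tags is available
  behind a flag (`sum_both_tags`) but is degenerate — it assigns both
  stimuli the same amplitude and all scores collapse to 0 — which is
  why per-own-tag is the default. Trial amplitudes are averaged within
  condition cells before the ratio is formed; rejected trials are
  excluded first. A zero denominator yields a missing value with a
  logged reason, never a silent 0.
- **ERD epochs start at −700 ms** even though scoring windows are
  unchanged: the −200–0 ms baseline must clear the wavelet support of
  the epoch edge, where the truncated wavelet's widened bandwidth
  inflates off-tone leakage power (a −0.06 log-power bias at gain 1
  without the pad; ≤ 0.02 error with it). ERD is computed on
  single-trial (induced) power — log per trial, baseline contrast per
  trial, then averaged — with an `evoked=True` flag for the
  average-then-transform alternative; log base 10.
- **SCR validity** is exact at the boundary: amplitudes ≥ 0.02 µS are
  valid ("below 0.02" excluded). Argmin/argmax ties resolve to the
  earliest sample; the peak search is restricted to samples after the
  valley. The 0.01–5 Hz conductance conditioning precedes scoring.
- **HR** interpolates instantaneous rate (60000/RR at beat times)
  linearly onto a 10 ms grid before window averaging; the method is a
  stated choice since beat-to-grid assignment is not standardized.
- **AUCi** references the second sample (the pre-stressor baseline of
  its own 2–6 window); `baseline_index=0` switches to the first sample.

## The ANOVA

The split-plot partition for one between factor (a groups, n_g subjects)
and up to two within factors (b, c levels): the group effect is tested
against subjects-within-groups; each within effect and its group
interaction against its factor × subject(group) stratum; the two-way
within interaction terms against the b×c×subject(group) residual.
Greenhouse–Geisser ε = tr(E)²/(df·tr(E²)) with E = MᵀSM, where M is the
orthonormal (Helmert) contrast basis of the effect and S the covariance
of subject cell scores pooled within groups (the convention of classical
split-plot software; estimators using the total covariance differ
slightly whenever group effects exist). ε is clipped to [1/df, 1] and is
exactly 1 for single-df effects; GG-corrected fractional dfs and p
values are reported for every within effect. Unbalanced or incomplete
data raise immediately — nothing is imputed. Post hoc contrasts are
paired/independent t-tests on cell means with Bonferroni correction over
the declared family, which is recorded with the output.

## Power calibration of the group effects

The recovery criterion asks that injected group effects be detectable in
at least 80% of simulated 40-per-group experiments. The defaults were
set analytically before any test was run: the group × hemifield contrast
reduces to a two-sample t on per-subject left-minus-right score
differences with mean 2β = 0.4 and SD ≈ √(4σ_β² + 2σ_cell²/3) ≈ 0.54,
giving d ≈ 0.74 and power ≈ 0.90 at n = 40/group; the ERP attenuation
(0.8 against subject σ = 0.25 lognormal) gives d ≈ 0.86, power ≈ 0.95.
Because running 100 experiments × 80 participants of full EEG synthesis
and scoring is hours of compute, the many-experiment studies draw
condition-cell summaries directly from the same parametric model
(`sample_bias_experiment`, `sample_erp_experiment`); a zero-noise test
verifies that the raw-EEG route reproduces the analytic cell scores that
the samplers draw around.

## Problem sizes used in the tests

Signal-level tests run 2–8 trials per condition at zero or low noise,
where recovery is exact up to stated tolerances; the end-to-end pipeline
test uses 2 participants per group with 8 ATB trials per combination and
4 viewing trials per expression; power studies use 100 amplitude-level
experiments at the full n = 40/group. The generator defaults themselves
(40 per group, 96 ATB trials per combination, 32 viewing trials per
expression) reflect the emulated study design.

## What passing tests do and do not show

The generator validates the *scoring machinery*: linear projections,
stationary narrowband oscillations, noiseless or Gaussian-noise
conditions, no ocular/muscle artifacts, no head-model forward
projection, no latency jitter in ERPs, a pure-tone alpha rather than
broadband rhythm. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
real-EEG pathologies (artifacts, drifting electrodes, latency
variability, alpha nonstationarity). Two quantified conservatisms carry
over to real use: the envelope noise floor and tag-frequency crosstalk
both shrink bias scores toward zero, so ABS magnitudes are lower bounds
on the underlying amplitude asymmetry. The inference layer is validated
independently of the generator (projection oracle, permutation null,
type-I calibration under nonsphericity).
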