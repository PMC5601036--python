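# Methods

`beatsync` measures how consistently a repetitive whole-body movement
(bouncing by knee flexion) is timed to an isochronous musical beat, from
motion-capture marker trajectories, and tests group-level differences in that
consistency. Because the original recordings this kind of study produces are
rarely shareable, the package pairs the analysis pipeline with a synthetic
movement generator whose ground truth is known exactly; every quantitative
guarantee the test suite makes is stated against that generator.

## Per-trial analysis model

A trial is a frames × markers × 3 array of positions (mm) at `fs` = 100 Hz,
with an accompanying beat timeline of `n_beats` isochronous onsets at tempo
110, 115 or 120 BPM (beat frequency `f0 = BPM/60` Hz). The analysis marker is
the right knee (`knee_R`), whose displacement is tightly constrained by the
bounce. The stages:

1. **Band-pass filter.** Each anatomical axis is filtered around `f0` with a
   total passband width of 20% of `f0` (edges `f0·(1 ± 0.1)`), realized as a
   2nd-order Butterworth applied forward and backward (`sosfiltfilt`). The
   zero-phase property matters: any filter lag would bias every relative
   phase by `2π·f0·lag`. The filter family is a conventional choice for
   kinematic data; the passband width is the analysis's defining constant and
   is exposed as `rel_bandwidth`. (An alternative reading of "20% bandwidth"
   as ±20% per side would double the width; we use total width, and the
   parameter makes the other reading one config change away.)
2. **Component selection.** The axis with maximal RMS of the *filtered*
   signal is kept. RMS rather than peak-to-peak because the latter is decided
   by single extreme samples. Exact ties (possible only in constructed data)
   break vertical > anteroposterior > mediolateral. Filtering precedes
   selection so that broadband noise on a quiet axis cannot out-vote the
   beat-band oscillation.
3. **Instantaneous phase.** The Hilbert analytic-signal phase, computed after
   mirror-padding 5 s per side and trimming, which confines the transform's
   circular edge distortion to the discarded margins. (Odd/anti-symmetric
   reflection is *not* used: it continues the oscillation time-reversed, a
   negative-frequency segment that contaminates the analytic signal far from
   the edge.)
4. **Beat sampling.** The unwrapped phase is linearly interpolated at beat
   onsets (onsets rarely fall on the 10 ms frame grid) and wrapped to
   (−π, π]. The first 10 beats (~5 s — time to find the beat) and the last 3
   (end-of-trial margin) are excluded; a 128-beat trial therefore yields 115
   phases. Both counts are parameters (`n_lead_excluded`, `n_tail_excluded`).
   Since the stimulus phase is 0 (mod 2π) at every onset, the sampled
   movement phase *is* the movement-to-beat relative phase.

## Circular statistics

With phases `θ_k`, `k = 1..n`, mapped to unit vectors:

- mean resultant `R = |n⁻¹ Σ e^{iθ_k}|` ∈ [0, 1], mean direction its argument;
- Rayleigh statistic `Z = nR²`, with
  `p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n))` (the standard series
  approximation, used for n ≥ 5; a Monte-Carlo null option exists for
  verification). A trial is **phase-locked** when `p < α` with α = 0.001.
- circular variance `V = 1 − R`;
- **synchronization consistency** `SC = −ln V` (base configurable). Across
  trials, V is lognormal-like (random-walk phase noise multiplies survival of
  the resultant), so the negated log yields an approximately normal score
  with higher = better — the acceptance checks verify |skewness| < 0.5. The
  score is reported only for phase-locked trials; `V = 0` (perfect lock,
  possible only in noise-free synthetic data) maps to +∞ with a warning.

## Group-level inference

Trials that are not phase-locked are excluded. Participants are excluded by
two rules, in order: (1) more than half of their trials not phase-locked;
(2) within designated cells (default: hearing group, auditory condition),
mean SC strictly below the group mean minus 2 SD, the SD computed including
the candidate (the convention is stated because the rule is ambiguous
otherwise; "exactly at the boundary" is retained). The up-to-two trials per
participant × condition × tempo cell are averaged.

Each group's cell means enter a two-way fully-within-subject ANOVA
(condition × tempo), computed from the definitional balanced-design
sums-of-squares partition with per-effect subject-interaction error terms,
`F = MS_effect/MS_error`, partial η² = SS_effect/(SS_effect + SS_error), and
*uncorrected* degrees of freedom (no sphericity correction): 14 subjects × 3
conditions gives df (2, 26). The implementation is cross-checked against
statsmodels' `AnovaRM` to 1e−8 in the test suite. Post-hoc comparisons are
paired t-tests on tempo-averaged condition means with Bonferroni–Holm
adjustment (the conventional follow-up; only the adjustment, not the test, is
dictated by the analysis plan). Missing cells are handled by listwise
deletion, which the balanced SS formulas require.

Between groups, the deaf group's two vibrotactile conditions (which do not
differ by design — deafness removes the auditory-leakage difference between
masking and earmuffs) are averaged per participant and compared with each of
the hearing group's vibrotactile conditions by a pooled-variance Student
t-test; 14 + 7 participants give df = 19 (pooled, not Welch — Welch df would
not generally equal 19).

## Synthetic generator

`simulate_bounce_trial` writes the dominant-axis displacement as
`A·cos(φ(t))` with `φ(t) = 2π f0 (t − t_first_onset) + lag + ε(t)` after a
startup transient; the cosine convention makes the Hilbert phase at beats
equal the generative relative phase directly. During `startup_s` (default
5 s, matching the 10 excluded lead beats) the instantaneous frequency ramps
linearly from the mover's own spontaneous tempo to the stimulus tempo. Two
noise processes:

- **random-walk phase noise** (`phase_noise_sd`, rad/√s): Brownian wander of
  the relative phase. This is the process that produces a lognormal-like
  spread of V across trials, and it dominates human-like trial-to-trial
  variability;
- **per-beat von Mises jitter** (`kappa`): fast timing scatter, used for
  mean-angle recovery checks (the 0.4 Hz-wide filter attenuates much of this
  fast jitter, which is physiologically sensible smoothing and leaves the
  mean lag unbiased).

Secondary axes carry a half-amplitude fundamental plus a second harmonic and
a small residual sway; default dominant axis is anteroposterior (knee moves
forward as it flexes) with vertical secondary. 28 markers are emitted by
default; only `knee_R` carries the full signal, the rest are attenuated
copies with static offsets plus the same broadband noise — marker-set
fidelity without biomechanics. `simulate_unsynced_trial` oscillates at the
mover's own tempo with a slow frequency random walk, uncoupled from the beat
(with own tempo = stimulus tempo and zero drift it is indistinguishable from
a locked trial, a documented degenerate case). All randomness derives from
one integer seed; identical inputs give bit-identical output.

### Cohort defaults (the simulated study conditions)

7 deaf + 14 hearing participants; deaf: mask + muff, hearing: mask + muff +
auditory; tempi 110/115/120 BPM × 2 trials per cell (12 and 18 trials per
participant; 336 total). Planted coupling, as phase-noise SD (rad/√s):
hearing auditory 0.06, muff 0.10, mask 0.14; deaf mask = muff = 0.14. This
encodes the qualitative pattern of interest: auditory > muff > mask within
the hearing group, no condition difference within the deaf group, a
deaf-vs-hearing gap in muff but not mask. Participant ability is a lognormal
multiplier (σ = 0.18) on the condition SD, and each participant gets a
stable preferred lag (≈ N(0.3, 0.25²) rad). The multiplier σ was fixed at
design time from a closed-form approximation of the Brownian-phase resultant
(R ≈ mean over the trial of e^{−s²t/2}) so that the planted muff gap has a
pooled effect size near d ≈ 1.5 — i.e., the planted effect is designed to be
detectable with ≥ 80% power at n = 7 vs 14, which is what the end-to-end
power check then verifies by simulation. With these defaults SC means land
around 2.9 (mask) to 4.5 (auditory).

What the generator does **not** emulate: biomechanical coupling between
markers (others are scaled copies), amplitude variability and fatigue drift,
movement dropouts/occlusions, tempo-dependent coupling, and any calibrated
match to human inter-trial variance (no distributional parameters of real
bouncing were available to fit). Passing tests therefore certify the
*analysis* — filters, phase extraction, statistics, exclusion logic — not a
claim that the simulator reproduces human movement statistics.

## Numerical and design choices

- Phases wrap to (−π, π] via `angle(e^{iθ})`; interpolation happens on
  unwrapped phase to avoid wrap artifacts.
- Filtering requires ≥ 10 beat periods of signal and a passband below
  Nyquist; degenerate inputs (all-constant marker, all-zero signal) raise
  typed errors rather than returning NaN.
- The Rayleigh series approximation's absolute error is ≲ 2×10⁻³ at n = 7
  and shrinks rapidly with n (verified against a 100k-draw Monte-Carlo null).
- `two_sample_t` returns t = 0, p = 1 for two identical constant groups
  (0/0 convention).
- Problem sizes in the verification experiments: 1,000 phase sets for oracle
  equivalence, 100k-draw Rayleigh nulls at n ∈ {7, 20, 115}, 10,000 uniform
  replicates for type-I calibration, 100 trials per phase-noise level for
  recovery/monotonicity, 50 random tables for the ANOVA cross-check, and 200
  simulated cohorts (single-marker trials — the pipeline only reads the knee
  marker) for the planted-effect power check.

## Known limitations

- The 3-beat tail exclusion (giving 115 of 128 analyzed beats alongside the
  10-beat lead exclusion) is an end-of-trial margin convention; both counts
  are explicit parameters.
- "SC" uses the natural log; any other base is a linear rescaling and is
  configurable (`sc_log_base`).
- The RM-ANOVA assumes a balanced complete design after listwise deletion
  and does not offer sphericity corrections or mixed-model alternatives.
- Group comparisons assume equal variances (pooled t); this is a modelling
  commitment, not a tested property of real data.
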