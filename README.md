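# beatsync

Movement–beat synchronization analysis for motion-capture experiments in
which participants bounce (knee flexion) in time with an isochronous beat —
heard as music or felt as floor vibration. The package takes marker
trajectories plus a beat timeline and answers two questions per trial: *was
the movement phase-locked to the beat at all?* and *if so, how consistently?*
— then aggregates those answers into group-level inference. It is aimed at
sensorimotor-synchronization researchers comparing synchronization quality
across stimulus modalities (e.g. auditory vs vibrotactile) and across groups
(e.g. deaf vs hearing participants).

## The analysis in brief

For each trial, the right-knee displacement is band-pass filtered around the
stimulus beat frequency f₀ (zero-phase 2nd-order Butterworth, total passband
width 0.2·f₀); the axis of maximal filtered amplitude is kept; the Hilbert
instantaneous phase φ(t) is sampled at beat onsets (discarding the first 10
and last 3 beats — a 128-beat trial yields n = 115 relative phases θₖ). Then,
treating phases as unit vectors:

- mean resultant **R** = |n⁻¹ Σₖ e^{iθₖ}|, Rayleigh **Z** = nR² with the
  series-approximate p-value; the trial is **phase-locked** if p < 0.001;
- circular variance **V** = 1 − R;
- synchronization consistency **SC** = −ln V (higher = more consistent; the
  log normalizes V's lognormal-like distribution across trials).

Group level: non-locked trials are dropped; participants failing to lock on
more than half their trials, or scoring below group mean − 2 SD in a
designated condition, are excluded; trial pairs are averaged per
condition × tempo cell; each group gets a two-way fully-within
repeated-measures ANOVA (condition × tempo, partial η², uncorrected df,
Holm-adjusted paired post-hocs), and groups are compared by pooled-variance
t-tests on tempo-averaged scores.

Because motion-capture recordings of this kind are rarely shareable, the
package includes a synthetic bouncing-movement generator
(`beatsync.synth`) with exactly known phase coupling — steady-state lag,
random-walk phase noise, per-beat von Mises jitter, startup transient, 28
emitted markers — so the entire pipeline is verifiable end to end against
ground truth. See `docs/methods.md` for the model, defaults and limitations.

## Worked example

Simulate the default cohort (7 deaf + 14 hearing participants, 336 trials of
128 beats at 110/115/120 BPM) and analyze it — either via the numbered
drivers:

```bash
python analysis/01_simulate_cohort.py   # trials -> scratch/cohort/
python analysis/02_analyze_trials.py    # per-trial stats -> results/trial_results.csv
python analysis/03_group_stats.py       # exclusions, ANOVAs, t-tests -> results/
python analysis/04_figures.py           # condition-mean figure
```

or the equivalent CLI (`beatsync simulate|analyze|report`). The group-stats
step prints, for the bundled simulation seed:

```
hearing: condition F(2,26) = 96.36, p = 9.47e-13, partial eta^2 = 0.88
deaf: condition F(1,6) = 0.01, p = 0.9285, partial eta^2 = 0.00
groups @ mask: t(19) = -1.44, p = 0.165 (hearing 2.79 vs deaf 3.11)
groups @ muff: t(19) = 1.52, p = 0.144 (hearing 3.46 vs deaf 3.11)
```

Reading it: the hearing group's synchronization consistency differs strongly
across stimulus conditions — the planted ordering auditory > muff > mask, df
(2, 26) from 14 participants × 3 conditions — while the deaf group's two
vibrotactile conditions are indistinguishable (F(1, 6) ≈ 0), as planted. The
between-group muff comparison (df 19 = 14 + 7 − 2) carries a planted true
difference of moderate size; in this particular simulated cohort it does not
reach 0.05 — single-cohort group tests at n = 7 vs 14 are detectably but not
overwhelmingly powered (the measured detection rate across 200 cohorts is
~0.8; see below).

In a library session:

```python
import beatsync as bs

stim = bs.generate_beat_onsets(tempo_bpm=120, n_beats=128)
params = bs.BounceParams(mean_lag_rad=0.3, phase_noise_sd=0.1, seed=7)
trial = bs.simulate_bounce_trial(params, stim)
res = bs.analyze_trial(trial, stim)
print(res.n, res.phase_locked, round(res.mean_angle_rad, 2), round(res.sc_score, 2))
# 115 True -0.51 5.38
```

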