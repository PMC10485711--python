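# Methods

`hrvgame` is the headless computational core of a cardiorespiratory
biofeedback serious game plus the analytics used to evaluate it in a
two-group, baseline/test pilot protocol. This note documents the models and
procedures, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Signal chain

**RR series.** The universal input is a beat-to-beat RR-interval series in
milliseconds. Beat *i* is timestamped at the *end* of interval *i*; beat
times are the cumulative interval sum, which makes them strictly increasing
by construction. Instantaneous heart rate is iHR = 60000 / RR (bpm).

**Artifact filter.** Chest-strap RR streams contain false-positive and
false-negative detections. The filter is a running-median ectopic-beat
heuristic: beat *i* is rejected when it deviates from the median of the
last `window` (default 5) accepted beats by more than `threshold` (default
25%, relative). The first two beats seed the accepted history — no median
is defined before that. Rejected beats are labelled `artifact` and, in the
default `interpolate` mode, replaced by linear interpolation between the
nearest accepted neighbours (label `interpolated`); replacement rather
than deletion keeps the tachogram contiguous for spectral analysis. A
`delete` mode is available behind the policy flag. When more than half of
the beats are rejected the recording is declared unusable. The filter is
idempotent and never alters beats it does not label; both properties are
tested. The 25%/5-beat rule is a conventional, deterministic stand-in for
whatever proprietary filter a commercial app applies; it is fully
configurable via `FilterPolicy`.

## HRV metrics

**Time domain** (over one recording segment, `artifact` beats excluded):
RR mean; SDRR with the N−1 denominator (a sample statistic over a finite
recording); RMSSD = sqrt(mean of squared successive differences); pNN50 =
percentage of successive differences strictly exceeding 50 ms.

**Frequency domain.** The unevenly sampled (beat time, RR) tachogram is
resampled at 4 Hz by cubic interpolation, linearly detrended, and its power
spectral density estimated with a Welch segment-averaged Hann-windowed
periodogram (120 s segments, 50% overlap). LF and HF are the absolute
powers (ms²) integrated over 0.04–0.15 Hz and 0.15–0.4 Hz by trapezoidal
quadrature. These are Task-Force-compatible conventions; the estimator,
window, segment length and band edges are configurable via
`SpectralConfig`. Normalized units and VLF are out of scope. Recordings
shorter than one segment raise an error rather than silently shrinking the
segment. The estimator is checked for energy consistency (band powers
bounded by total power; total power within 10% of the detrended resampled
tachogram's variance) and amplitude scaling (doubling the modulation
amplitude quadruples in-band power).

## Level geometry and calibration

A level is built from a prerecorded RR series: its per-beat iHR is linearly
interpolated and sampled at the centre of each 1-second column, giving a
target curve with `floor(recording span)` columns (span counted from time
zero).

Calibration maps iHR to normalized screen position. Over a rest window
(≥ 10 beats; 30–40 s in practice), `baseline_ihr` is the mean per-beat iHR
and `half_range` is `k` (default 2) sample SDs of per-beat iHR, floored at
5 bpm so a near-constant window still yields a playable span. The mapping
is linear: `y = 0.5 + sign · (iHR − baseline) / vertical_extent`, clipped
to [0, 1]; the baseline maps exactly to the screen centre. The screen's bpm
extent defaults to `2 · 3 · half_range`, i.e. proportional to the player's
own variability — the "screen adjusted to the range of variability" rule,
interpreted as vertical scaling since vertical position is the only
physiologically driven axis.

Level equity: before mapping, the reference curve is re-anchored onto the
player's baseline. The default anchor is the curve's *first* value, so
every player starts exactly at the screen centre and faces the same
relative excursions; anchoring on the curve mean (or no anchoring) is
available. The corridor is `target ± corridor_half_width` (default 5 bpm,
normalized by the extent); targets are clipped so the corridor always fits
strictly inside the screen. Obstacles tile the whole space outside the
corridor — collision only depends on the corridor bounds, so dense tiling
is equivalent to the sparse art placement of a rendered game and simpler. A
bonus sits on the target every `bonus_spacing` (default 5) seconds. Tracks
serialize to versioned JSON with hex-encoded floats, round-tripping
bit-exactly.

## Game loop

The loop is deterministic and tick-based (default 10 Hz). The per-beat iHR
stream is resampled to the tick grid by sample-and-hold, matching per-beat
delivery from a live sensor. Each tick: position from the calibrated
mapping; contact with the space outside the open corridor costs one life,
followed by a 1 s invulnerability window (without it, a single obstacle
would drain all lives in a few ticks — how continuous contact maps to
discrete losses is a design choice, made explicit here); the bonus on a
column is collected once when the avatar passes within `bonus_tolerance`
(default 0.1 normalized) of the target. Games start with 20 lives and end
in `completed` (end of track, ≥ 1 life) or `game_over` (no lives). A
microsecond tolerance in the column lookup absorbs the floating drift of
the accumulated tick clock at column boundaries.

The final-page summary reports bonus count, time played, average HR of the
consumed samples, and a stress index. The stress index is the Baevsky
histogram index, SI = AMo / (2 · Mo · MxDMn) on the consumed RR
equivalents with 50 ms bins and the range floored at one bin width; the
quantity a deployed game labels "stress index" is not standardised, so the
implementation is explicitly a conventional stand-in and pluggable through
`run_game(stress_index_fn=...)`.

## RSA simulator and player models

The generator builds RR series beat by beat:
`RR(t) = mean_rr + A · w(f t) · g(t) + Σ offsets(t) + N(0, σ)`, advancing
each beat time by the generated interval. `w` is a deterministic
asymmetric sinusoid whose inhalation:exhalation ratio shapes the
within-cycle waveform — a controllable stand-in for respiratory sinus
arrhythmia, not a physiological coupling model. Technique events emulate
the voluntary manoeuvres players use: apnea adds `+magnitude` ms (iHR
falls) and multiplies the respiratory swing by 1.5; mild hyperventilation
adds `−magnitude` and suppresses the swing to 0.25; muscle movement and
swallowing inject brief biphasic transients (opposite polarity orders).
Events ramp on and off with half-cosine edges. Magnitudes are
configuration, not physiological claims; their defaults are chosen to
reproduce the *direction* of the pilot findings (RR mean and RMSSD fall
under hyperventilation). A beat at or below 200 ms raises an error.

Player models: the *perfect* player inverts the screen mapping onto each
column's target (an oracle that by construction never touches an obstacle
and collects every bonus); the *noisy* player adds AR(1) tracking error
(coefficient 0.7) with stationary SD `(1 − skill) · half_range`, so
`skill = 1` reproduces the perfect stream and bonus count increases
statistically with skill.

**Cohort simulator.** `simulate_cohort` reproduces the pilot protocol:
two groups (control / experimental) of `n_per_group` (default 8)
participants; two recorded games per phase on two shared levels, played in
the baseline phase and again in the test phase. Per participant,
physiology is drawn once (mean RR ~ N(850, 60) ms clipped to 600–1100,
respiratory rate ~ U(0.20, 0.30) Hz, RSA amplitude ~ N(40, 8) ms, 15 ms
beat noise) and a 40 s rest recording yields the session calibration.
Baseline tracking skill is U(0.35, 0.65); both groups gain skill in the
test phase through practice (+0.05), the experimental group more (+0.15,
it was taught the techniques) plus scheduled hyperventilation events
(2 × 40 s, 80 ms) in its test recordings. Each game pairs a generated RR
recording (filtered, then HRV metrics with 60 s Welch segments — the
games are 120 s long) with a noisy-player game run. Defaults are the study
conditions; `null_effects()` gives the zero-group-effect configuration
used for the false-positive calibration check.

What the generator does *not* emulate: baroreflex/LF oscillatory dynamics,
breathing-rate drift, circadian or postural effects, sensor dropout
bursts, or any coupling between game events and physiology (the
performance and physiology channels are conditionally independent given
the participant). Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and the recoverability of planted effect directions,
not physiological realism.

## Study aggregation

Per-phase records average each participant's games within a phase (exactly
`games_per_phase`, default 2, enforced with a named error). The group
change table reports cell means and SDs per group × phase, within-group
deltas (test − baseline), the between-group difference of test-phase
means, and the delta-of-deltas (the group-by-phase interaction a factorial
model would test). The parametric 2 × 2 MANOVA itself is routine
inferential statistics and deliberately not re-implemented; instead a
self-contained permutation test of the interaction (group labels permuted
across participants, default 10 000 permutations) is provided.

Whole-sample descriptives are reconstructed from per-group moments with
the exact pooling identity
`SS_total = Σ[(n_i − 1) s_i² + n_i (m_i − M)²]`, `variance = SS_total /
(N − 1)` — identical to concatenating the raw samples, verified against
explicitly constructed samples to 1e-9.

Session export is a versioned JSON document; a deny-list of identifying
field names (name, email, birthdate, ...) is enforced at write *and* read,
implementing the anonymized-export contract at the schema level.

## Problem sizes and tolerances

Tests and the acceptance script use: 300 s recordings for spectral
localization (a 0.10 Hz modulation must exceed the other band's power
fivefold; noise-free localization margins are orders of magnitude wider);
100 random series against the brute-force time-domain oracle at 1e-9
relative tolerance; 50 cohort replicates for planted-sign recovery (≥ 90%
required); 60 null cohorts for the false-positive check with an a-priori
binomial bound (Bin(60, 0.05), bound 9 ≈ +3.5 SD); 10–50 game seeds for
skill monotonicity (Spearman ρ > 0.8). Published-table arithmetic (bonus
deltas 4.25 / 1.31, test-phase time difference 7.62 s, pooled N = 16
descriptives) is exact to the printed precision.

## Known limitations

- The artifact rule, spectral estimator details, stress index, tick rate,
  bonus-scoring geometry and calibration window length of the original
  deployed app are not public; each is implemented as a documented,
  configurable convention and the defaults are stated above.
- Obstacle tiling is dense; a renderer would subsample it for art
  placement.
- The simulator's group effects are directional by construction; effect
  *magnitudes* in simulated tables are not calibrated to any real cohort.
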