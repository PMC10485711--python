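# hrvgame

Headless core of a cardiorespiratory biofeedback serious game, plus the
heart-rate-variability (HRV) analytics and study aggregation used to
evaluate it.

In the game, a player's instantaneous heart rate — iHR = 60000 / RR, in
bpm, derived live from chest-strap RR intervals — steers an avatar up and
down a corridor generated from a *prerecorded* RR series. Staying on the
target waveform (by paced breathing, breath holds, or mild
hyperventilation) trains voluntary HRV self-regulation. This package
implements everything behind the screen, with no hardware or rendering:

- **`rr_signal`** — RR-interval file ingestion, validation, running-median
  artifact filtering with interpolation, iHR conversion;
- **`hrv_metrics`** — time-domain metrics (RR mean, SDRR, RMSSD, pNN50)
  and absolute LF (0.04–0.15 Hz) / HF (0.15–0.4 Hz) band powers from a
  Welch spectrum of the 4 Hz cubic-resampled tachogram;
- **`track_builder`** — player calibration (baseline iHR, variability
  half-range), reference curve on a 1 s grid, corridor/obstacle/bonus
  geometry, bit-exact JSON track files;
- **`game_engine`** — deterministic 10 Hz game loop: position mapping
  `y = 0.5 + sign·(iHR − baseline)/extent`, lives (20 at start),
  invulnerability windows, bonus collection, Baevsky stress index;
- **`rsa_simulator`** — synthetic RR generator with respiratory sinus
  arrhythmia (asymmetric sinusoid), technique events (apnea,
  hyperventilation, muscle, swallow), perfect/noisy player policies, and a
  two-group baseline/test cohort simulator;
- **`study_pipeline`** — anonymized session export, per-phase averaging,
  group change tables, exact pooling of per-group descriptive moments, and
  a permutation test of the group-by-phase interaction.

It is aimed at researchers prototyping HRV-biofeedback protocols and at
anyone needing a reproducible, fully scriptable stand-in for the deployed
game.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import hrvgame as hg

# 5 minutes of synthetic RR intervals, paced at 0.1 Hz (LF band)
rr = hg.generate_rr(
    hg.SimConfig(mean_rr=850, noise_sd=15, duration=300, seed=7),
    hg.BreathingPattern(freq=0.1, amplitude=50),
)
filtered, report = hg.filter_artifacts(rr)      # report.n_rejected == 0
print(hg.hrv_metrics(filtered).as_dict())

cal = hg.calibrate(filtered)                    # baseline 70.99 bpm, half-range 6.32
track = hg.build_track(hg.build_reference_curve(filtered), cal)
stream = hg.noisy_player_stream(track, cal, skill=0.7, seed=1)
print(hg.run_game(stream, track, hg.GameConfig(), cal))
```

prints (rounded):

```
{'rr_mean': 846.9, 'sdrr': 37.65, 'rmssd': 26.79, 'pnn50': 6.5,
 'lf_power': 1274.02, 'hf_power': 84.53}
GameResult(bonus=60, time_played=300.0, avg_hr=66.37,
           stress_index=82.45, completed=True, lives_left=20)
```

The 0.1 Hz pacing concentrates spectral power in the LF band (1274 vs
85 ms²). The track is 300 columns long with a bonus every 5 s (60 total);
a skill-0.7 player tracks the target well enough to collect all 60
bonuses and finish with all 20 lives.

The same flows are scriptable from the shell:

```sh
hrvgame simulate rr --duration 300 --breathing-freq 0.1 --out rec.txt
hrvgame hrv compute rec.txt
hrvgame track build rec.txt --out level.json
hrvgame play level.json --player noisy --skill 0.7 --seed 1
hrvgame simulate cohort --n-per-group 8 --seed 0 --out cohort/
hrvgame study aggregate cohort/games.csv --out tables/
```

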