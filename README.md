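# soundseek

A simulation and analysis stack for **sound-seeking**: a freely-moving
auditory task in which a mouse explores an octagonal eight-chamber arena to
track down an ongoing sound stream and poke the port beneath the goal
speaker. The package is aimed at behavioral neuroscientists who run (or
model) this kind of task and need a tested, reproducible pipeline for every
computational stage — stimulus generation, trial adjudication, performance
scoring, trajectory-based strategy metrics, startle quantification, and
auditory brainstem response (ABR) preprocessing — together with a
synthetic-data module (agents, trajectories, ABR epochs) that stands in for
live animals so every stage is verifiable at desk scale.

## The task and its metrics

On each trial one of 8 speakers (the *goal*) plays a stream of 10 ms
narrowband noise bursts until the goal port is poked; wrong pokes trigger an
error tritone but never end the trial, the goal never repeats on consecutive
trials, and the next trial starts 1 s after reward.

**Stimulus.** Inter-burst intervals are i.i.d. gamma draws, moment-matched
so rate and irregularity are independent: with mean interval
μ = 1000/rate ms and SD σ (the irregularity),

    shape k = μ²/σ²,   scale θ = σ²/μ.

The fixed task uses 4 Hz, σ = 31.6 ms, 70 dB SPL, 10 kHz; the variable task
draws log-uniformly from 3–10 Hz, 1–100 ms, 65–90 dB SPL, 5–15 kHz per trial.

**Scoring.** Pokes into the previously rewarded port and duplicate pokes are
disregarded; *ports poked per trial* is the goal's rank among the remaining
distinct ports (1 = perfect, 7 = maximum — 8 is unreachable), and a trial is
*correct* when that rank is 1. Any sound-independent strategy scores
E[ports poked] = 4 and P(correct) = 1/7 ≈ 0.143, because the goal's rank
among the 7 eligible ports is uniform.

**Trajectories.** Chamber entries (first frame the snout passes into a
chamber) are classified as duplicates, returns to the previously rewarded
chamber, *cycling* (ring-adjacent to the chamber just exited; 2/7 under a
uniform null), and entries with poke vs. *checks* (entries without poke).
Center paths are scored by mean speed and straightness
D_straight / D_actual ∈ [0, 1].

**Startle.** Whole-body movement is the per-frame distance moved by each
tracked body part, averaged over parts; the startle magnitude is the mean
movement over the 5 frames (167 ms at 30 fps) after stimulus onset.

**ABR.** Click-evoked two-channel epochs at 16 kHz are processed by
least-squares FIR cross-talk removal (speaker → neural), zero-phase 100 Hz
high-pass, rejection of the top 5% of epochs by peak-to-peak excursion or by
SD (union), and averaging with left-side responses inverted so Wave 1 is
positive.

## Worked example

```python
from soundseek import task, poke_metrics as pm, entry_metrics as em
from soundseek.agents import make_agent

log = task.run_session(make_agent("expert"), 2000, seed=11)
print(pm.session_summary(log))
# {'subject': 'sim', 'session_idx': 0, 'condition': 'pre', 'n_trials': 2000,
#  'n_incomplete': 0, 'fraction_correct': 0.567, 'mean_ports_poked': 1.8335}

log = task.run_session(make_agent("bilateral_post"), 2000, seed=11)
per_trial = [em.classify_entries(em.entries_from_trial(t), trial=t,
                                 with_poke_known=True) for t in log.trials]
print(em.entry_rates(per_trial))
# {'n_trials': 2000, 'duplicates_per_trial': 0.0, 'prev_return_fraction': 0.0,
#  'p_cycling': 1.0, 'entries_with_poke': 4.01, 'entries_without_poke': 0.0,
#  'total_nonexcluded_entries': 4.01}
```

The expert agent plateaus near 1.8 ports poked per trial (≈ 0.8 wrong pokes
before the goal). The post-bilateral-hearing-loss agent cycles around the
ring (p_cycling = 1), pokes every port in turn, and lands exactly at the
chance level of 4 ports poked with no checks — a routinized exhaustive
search.

A CLI wraps the same library:

```sh
soundseek simulate --preset expert --trials 500 --seed 1 --out out/run
soundseek score --log out/run --out out/scores.csv
soundseek report --trials 2000 --seed 1 --out out/report
```

## Analysis pipeline

Numbered drivers under `analysis/` rebuild the full study storyline on
synthetic data and write tidy tables and figures under `results/`:

1. `01_simulate_behavior.py` — cohorts learning the task, then sham /
   unilateral / bilateral hearing-loss phenotypes.
2. `02_learning_curves.py` — Gaussian-smoothed (SD 50 trials) learning
   curves and the 2.5-ports-poked criterion session per mouse.
3. `03_trajectory_metrics.py` — entry taxonomy, center-path speed and
   straightness, stillness by region, from rendered pose tracks.
4. `04_startle_metrics.py` — startle magnitudes across the surgery timeline
   (preserved after unilateral, abolished after bilateral loss).
5. `05_abr_pipeline.py` — ABR pipeline over a 0–55 dB attenuation grid;
   recovered wave amplitude tracks 10^(−attenuation/20).

Each accepts `--seed` and `--out-dir`.

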