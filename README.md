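# songdrift

Subunit-weighted drift-diffusion analysis of mate-choice decisions in the
grasshopper *Chorthippus biguttulus*.

Females of this species answer a male calling song with a response song
when they judge it attractive. Playback experiments probe that decision
with song models built from exactly two subunit types (syllable + pause
units) — one attractive, one unattractive — mixed in varying proportions
and placements over 33 subunits. This package implements the computational
side of that paradigm for modellers of acoustic communication and
decision-making:

* construction of the stimulus sets (subunit timing/level catalogue, song
  assembly, amplitude envelopes);
* a discrete-step drift-diffusion model of the response decision: subunit
  *k* contributes a signed weight ω plus Gaussian noise σ to an evidence
  total E_k that starts at 0 and accumulates without leak between two
  absorbing thresholds θ⁺ and θ⁻ (strict crossing fixes the decision;
  otherwise the sign of E_33 decides), with both a Monte-Carlo simulator
  and a deterministic density-propagation backend;
* fitting of the subunit weights (block subunit anchored at ω = +1.0) and
  the shared integrator (σ, θ⁺, θ⁻) to per-song response rates by a genetic
  algorithm with ratio-space refinement, leave-one-out cross-validation,
  and a per-set-integrator model comparison;
* a synthetic-cohort generator with the experiment's structure (35 songs
  per set, 18 presentation cycles, 12–22 females, negative-control
  exclusion rule) for parameter-recovery studies;
* derived decision-dynamics summaries: weight balances ω⁻/ω⁺,
  subunits-to-threshold counts, noise-to-signal ratios, first-passage
  profiles and their per-third decompositions.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

At the reference parameter set (block weight +1.0; heterospecific-like
subunit weights −82 and −87; σ = 142; θ⁺ = 420; θ⁻ = −803):

```python
>>> import songdrift as sd
>>> params = sd.REFERENCE_PARAMS
>>> song = sd.SongModel("dorsatus-pure", ("dorsatus",) * 33, "dorsatus")
>>> traj = sd.integrate_deterministic(song, params)
>>> traj.absorbed_at, traj.crossed
(10, 'lower')
```

Ten consecutive dorsatus-like subunits drive the noise-free evidence past
the rejection threshold — an early, irreversible veto — while the most
attractive subunit needs almost the whole song:

```python
>>> sd.subunits_to_threshold(15.0, params.theta_plus)   # onset-9dB weight
29
>>> sd.threshold_ratio(1.0, params.theta_plus)          # block subunit
420.0
>>> sd.noise_to_signal(params.sigma, -82.0)
1.7317...
```

With noise (σ/|ω| > 1.6 for every subunit), decisions are probabilistic;
the two backends agree:

```python
>>> switch = sd.build_song("switch-at-11-reversed", ("block", "mollis"))
>>> sd.response_probability_exact(switch, params)
0.09162...
>>> sd.response_probability_mc(switch, params, sd.DynamicsConfig(seed=3))
(0.093, 0.0012988...)
```

The analysis itself lives in numbered drivers:

```
analysis/01_build_stimuli.py        # 7 sets x 35 songs, timing checks
analysis/02_decision_metrics.py     # weight balances, crossing counts, NSR
analysis/03_integration_dynamics.py # switch-song trajectories and thirds
analysis/04_synthesize_cohort.py    # synthetic behavioral cohort
analysis/05_fit_and_recover.py      # GA fit + recovery report
```

each printing its findings and writing tables under `results/`. A
`songdrift` command-line tool wraps the same stages
(`generate-stimuli`, `synth-data`, `simulate`, `fit`, `crossvalidate`,
`dynamics`, `report`, and `run` for the full pipeline with a manifest).

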