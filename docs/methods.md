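# Methods

## The decision model

Female *Chorthippus biguttulus* grasshoppers answer a male calling song with
a response song when they judge it attractive. The package models that
decision as discrete-time evidence accumulation over the song's subunits
(syllable + pause units; 33 per song model). Subunit *k* of type ℓ adds a
signed weight ω_ℓ plus Gaussian noise:

    E_0 = 0,   E_k = E_{k−1} + ω(ℓ_k) + ξ_k,   ξ_k ~ N(0, σ²)

Integration is perfect (no leak): memory in this paradigm is long relative
to song duration. The decision is fixed irreversibly at the first step where
E_k **strictly** exceeds the upper threshold θ⁺ > 0 (respond) or falls
strictly below θ⁻ < 0 (reject); the evidence is clamped at the threshold
thereafter. If no threshold is crossed by song end, the sign of E_L decides
(respond iff E_L > 0; the measure-zero tie maps to reject). The model's
clock is the subunit index: one noisy increment per subunit regardless of
its physical duration (240 ms mollis subunits and 84 ms block subunits both
count one step).

Strict crossing matters for the noise-free arithmetic: with ω = 15 and
θ⁺ = 420, 28 subunits reach exactly 420 and do *not* fix the decision; the
29th does. The same convention makes the dorsatus (ω = −82) and mollis
(ω = −87) subunits fix a rejection at step 10 against θ⁻ = −803.

The weight of the standard block subunit is anchored at +1.0 and defines
the evidence unit; all other weights, σ and the thresholds are expressed in
that unit.

## Stimuli

Eleven subunit envelope definitions cover the ten tested types (the block
appears in a 72+12 ms and, paired with dorsatus, a duration-equalised
76+14 ms variant). Timing and levels are amplitude-envelope annotations
(64 dB SPL plateau by default; accented subunits use 70/82/58 dB, onset
accents 67/73 dB); silence is a distinguished level, not −∞, and no audio
is synthesised. Songs are label sequences assembled from placement
descriptors: the two pure songs, the two valence-switch songs (switch after
round(L/3) subunits, 11 at the default L = 33), blocked negative thirds,
and uniformly random placements at a given negative proportion p (exactly
round(p·L) negative subunits). A default family of 35 descriptors per set
spans proportions 0–100%. The exact mixture sequences of the original
experiments are unpublished; the parametric family reproduces their
described statistical structure, and the gap subunit's internal layout
(two 2-ms gaps by default) is likewise a documented emulation.

## Response-probability backends

* **Monte-Carlo** — vectorised simulation of the recursion; default 50,000
  repetitions for mean-trajectory plots, binomial standard errors reported.
* **Density propagation ("exact")** — the evidence density is tracked on a
  bin grid spanning the open interval (θ⁻, θ⁺), built with 0 and both
  thresholds as exact bin edges (bin width ≈ σ/20 by default, capped at
  4000 bins). Each step shifts by ω, convolves with the Gaussian kernel via
  CDF differences (midpoint rule), and books the mass beyond either
  threshold as absorbed using exact Gaussian tails. Absorbed mass is
  recorded per step, giving first-passage profiles and mean clamped
  trajectories as by-products. Because interior bin masses telescope, the
  single-step probability is exact to machine precision (Φ(ω/σ) for
  unreachable thresholds), and halving the bin width changes 33-step
  response probabilities by < 10⁻⁴ at the default resolution.

The two backends agree within Monte-Carlo error on random instances; the
density backend is deterministic and serves as the fitting objective.

## Fitting

The observable is the per-song response rate (fraction of presentations
answered, averaged over a cohort's females). The default objective is the
mean squared error between the density-backend response probability and the
observed rate; a binomial log-likelihood weighted by n_females × n_cycles
is available. The integrator (σ, θ⁺, θ⁻) is shared across stimulus sets;
per-set weights are free, block fixed at 1.0. Bounds: weights [−200, 50],
σ (0, 500], θ⁺ (0, 2000], θ⁻ [−5000, 0).

### Identifiability structure

Predictions depend on the free parameters almost entirely through the
ratios ω/σ and θ/σ; the *overall evidence scale* is pinned only through the
anchored block weight, whose drift (1 per subunit) is small against
σ = 142. Two consequences shape both the optimiser and the recovery
expectations:

1. The loss surface has a long, shallow, slightly curved valley along the
   scale direction. At the reference study size (7 sets × 35 songs, 20
   females × 18 cycles) the scale carries a statistical SE of ≈ 26% per
   cohort, and in roughly one cohort in five the global optimum is the
   "anchor-free" boundary solution (all parameters scaled up until weights
   pin at their bounds, block effectively irrelevant). Ratios, by contrast,
   are recovered to a few percent.
2. θ⁻ is identified only up to a lower bound: once deep enough to prevent
   early negative fixation, further deepening barely changes predictions.
   `profile_theta_minus` exposes the flat-below/steep-above profile, and
   recovery reports flag on-shelf estimates as `bounded_only`.

### Optimiser

The global stage is a real-coded genetic algorithm (tournament selection,
uniform crossover, decaying Gaussian mutation, elitism; defaults
population 200 × 300 generations, convergence window 25 at 10⁻⁶) run over
ratio coordinates at a fixed reference scale — in raw coordinates the GA
reliably stalls partway up the scale valley. Local refinement then proceeds
in three deterministic stages: a short σ-profile (the GA solution rescaled
to a geometric σ grid and refit at fixed σ by per-set Brent/simplex sweeps,
which is fast because each set's weights only touch that set's songs),
Powell conjugate-direction minimisation over (ratios, log σ) — the
canonical derivative-free method for curved shallow valleys; bounds are
enforced by clipping during assembly because scipy's bounded Powell variant
proved unreliable — and a short warm-started Powell pass on a finer density
grid (σ/12 bins) to remove the coarse fitting grid's small discretisation
bias. Solutions pinned against the weight or σ bounds are retried once from
a down-scaled start so the interior basin wins whenever its loss is lower.
The whole pipeline is deterministic given the seed. On noise-free data it
recovers all parameters to ≲ 1%.

Reduced search budgets (e.g. population 48 × 30 generations) are used for
the packaged recovery studies and tests; they reach the same optima on
these problem sizes in a few minutes per cohort on one core.

### Cross-validation and comparison

Leave-one-out cross-validation fits each fold on N−1 songs and predicts the
held-out song; r² is the coefficient of determination of held-out
predictions against observations, and parameter summaries are means ± SD
over folds. If removing a song strips its subunit from the training set,
that weight is carried from a full-data fit and flagged. The
shared-integrator and per-set-integrator model classes are compared on
identical folds by held-out MSE with a bootstrap CI over records; no
selection is forced.

## Synthetic cohorts

Each stimulus set is tested by its own cohort (as in the experiment).
Response counts are Binomial(n_cycles, p_truth) per female and song, with
p_truth from the density backend at the generating parameters; stimulus
order effects are not modelled (presentation order was randomised per cycle
precisely to suppress them). A 3-s unmodulated-noise negative control with
response probability 0.02 screens females: more than 2 responses out of 18
excludes the female before averaging (expected exclusion fraction
1 − BinomCDF(2; 18, 0.02) ≈ 0.5%). Optional per-female logit-normal
heterogeneity in p_truth (off by default) exists to stress-test fitting.
The motivation song preceding each cycle has no analysed response and is
not modelled. What passing recovery tests show is therefore conditional on
these assumptions — real cohorts add female-level heterogeneity, motivation
drift and order effects that the generator deliberately omits, and the
generator cannot be calibrated to the real data's variance because per-song
response rates were never published.

## Recovery study results and their interpretation

With the protocol frozen in the acceptance tests (cohort seeds 0–4), the
five independent cohorts gave per-seed scale errors between −30% and +125%
(the +125% being one boundary escape), while the means over seeds landed
within +6.8% (σ), +5.9% (θ⁺) and ≤ 9.7% (every weight). This is the
expected behaviour given the ~26% per-cohort scale SE: the *mean* recovers
the truth, single cohorts do not pin the scale. θ⁻ estimates track the
fitted scale (depth-to-noise ratio −5.1 to −5.9 against the true −5.65) and
are accepted anywhere at or below 80% of the true depth.

## Numerical and design choices

* Strict threshold crossing (ties do not absorb); for σ > 0 the difference
  has measure zero.
* Drift and noise are added jointly within a step; thresholds are tested
  once per step.
* E_L = 0 at song end maps to reject (conservative no-response default).
* Density grid: 0 and both thresholds are exact bin edges; absorbing tails
  use closed-form Gaussian CDFs rather than grid bins beyond the
  thresholds.
* Fitting grids: σ/5 bins (≤ 96) during search, σ/12 bins (≤ 320) for the
  final refinement and all reported predictions.
* Two threshold-distance conventions are reported deliberately: the integer
  strict-crossing count floor(|θ/ω|)+1 and the raw ratio |θ/ω| (420 for the
  block subunit), since both conventions are in common use.
* Ratios in summary tables are rounded to one decimal; machine outputs keep
  full precision.

## Known limitations

* The scale weak-identifiability above is a property of the experimental
  design (only the anchored block weight carries scale information), not of
  the implementation; conclusions should be drawn from weight *ratios* and
  from means over replicate cohorts.
* The parametric stimulus generator emulates, but cannot reproduce, the
  unpublished original mixture sequences.
* No reaction-time likelihood, collapsing bounds, leaky integration or
  continuous-time variant is provided; the model class is fixed to perfect
  accumulation with static thresholds.
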