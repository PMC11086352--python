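# Methods

## Model

An N-channel EMG envelope `Y` (channels × samples) is modelled as a linear
combination of M muscle synergies driven by rectified activations:

    Y ≈ W C,    C ≥ 0,    W free sign.

The nonnegativity constraint sits on the activations only: a synergy cannot
be "negatively recruited", but a recruited synergy may *suppress* a muscle,
which appears as a negative weight (an inhibitory component). With the bias
removed and an identity output nonlinearity, the Gaussian maximum-likelihood
problem is `min ‖Y − WC‖²_F` subject to `C ≥ 0`. We solve it by alternating
minimization:

* **C-step** — exact nonnegative coordinate descent over the rows of `C`
  (each row update is the closed-form minimizer clipped at zero; two sweeps
  per outer iteration), so the objective never increases;
* **W-step** — unconstrained least squares `W = Y Cᵀ (C Cᵀ)⁻¹`, with a
  ridge fallback (`λ = 1e−8`, logged) if `C Cᵀ` is singular.

Convergence: relative objective change < `tol` (default `1e−8`) or 500
iterations. Because the W-step is exact and the C-step monotone, the
returned `R²` is never below the initialization's.

**Seeding protocol.** NMF (multiplicative Frobenius updates, random
nonnegative initialization scaled to the data) is run 100 times; the 10
repetitions with the highest `R²` initialize the free-sign refinement. The
dimensionality is the smallest M at which *all* 10 refined solutions reach
`R² ≥ 0.8` (ascending search). The 10 solutions are column-matched to the
best one by maximum-cosine optimal assignment, averaged, each averaged
synergy divided by the standard deviation of its weights ("variance
normalized"), and the activations refit by nonnegative least squares
against the averaged `W`. Matching is needed because scale and permutation
are the model's only ambiguities — with `C ≥ 0` there is no sign-flip
ambiguity, so recovery is assessed by *matched* (not absolute) cosine.

`R² = 1 − SSres/SStot` with `SStot` centered per channel (the classical
coefficient of determination). An uncentered variant is available
(`centered=False`) since both conventions occur in the synergy literature.

When a synthetic free-sign forward model dips below zero (measured
envelopes never do), the NMF seeding stage operates on the rectified part
of the signal while the refinement sees the full signal.

## Preprocessing

`clean_raw`: IIR notch (Q = 30) at the power-line frequency and its first 3
harmonics, 4th-order Butterworth band-pass 20–400 Hz, mean removal — all
filters applied forward–backward (zero phase). `make_envelope`: full-wave
rectification, zero-phase 4th-order low-pass at 40 Hz, per-channel minimum
subtraction, centered 20 ms moving-average integration (a
non-overlapping-window decimation mode exists but the rate-preserving
smoother is the default, keeping concatenation and `R²` comparisons
rate-consistent). `condition_envelope`: samples above
`median + 5·MAD` per channel are replaced by their 5-sample neighbourhood
median, then each channel is divided by its standard deviation; a
zero-variance channel raises an error naming the dead electrode.
`segment_and_concatenate`: runs in which every channel is constant (or
zero) for longer than 0.5 s are excised — a flatline rule standing in for
manual dropout inspection — and repeated trials of the same
(subject, side, task, style) are concatenated. Variance normalization is
applied to the concatenated trial, and envelopes are not downsampled before
factorization.

## Synthetic cohorts

The generator emulates a two-side, multi-subject recording session:
14 muscles per side, 10 subjects in three age groups (4 under 30, 5 between
30 and 50, 1 over 50) and two expertise groups, five tasks (three scales
repeated twice per style, two pieces once) at four tempo–force styles,
60 s trials at a 100 Hz envelope rate.

* **Templates** (`make_synergy_bank`): unit-norm columns with ~4 dominant
  muscles each (dealt round-robin so supports barely overlap, as real
  shoulder/forearm modules do), small positive background weights, and
  `round(0.2·N)` strictly negative entries placed among non-dominant
  channels with minor magnitudes. Each channel's summed positive weight is
  kept ≥ 8× its summed negative magnitude: inhibition modulates an
  otherwise dominant positive drive, which also keeps the linear model's
  negative excursions negligible. Banks are redrawn until pairwise column
  cosines stay below 0.8.
* **Activations** (`simulate_activations`): white noise, Gaussian-smoothed
  (100 ms), restandardized, shifted by `activation_shift = 0.3` and
  rectified, with bursts saturating at 3 standard units. The shift sets the
  duty cycle (~60%); activations still spend substantial time at exactly
  zero, which is what makes the semi-nonnegative factorization identifiable
  — with activations bounded away from zero a continuum of equal-fit
  solutions exists and small negative weights are unrecoverable in
  principle.
* **Envelopes**: `Y = W C + ε`, `ε ~ N(0, 0.02²)`, floored at zero in
  cohorts (physical envelopes are nonnegative; the clipped mass is
  negligible by the dominance construction). Recovery benchmarks feed the
  unfloored noiseless model directly.
* **Individuality**: per-entry lognormal jitter on the weights, σ = 0.1
  between subjects and σ = 0.05 between trials. Trial-level jitter is what
  gives within-subject replicates independent errors, so paired tests are
  calibrated.
* **Planted effects**: a group effect scales the negative entries of the
  designated group's templates by `(1 + proportion_effect)`; a style effect
  adds a fixed shift to one (template, channel) at fast (tempo contrast) or
  soft (force contrast) trials. Every planted effect is recorded in the
  cohort manifest.

What the generator does **not** emulate: task-locked activation waveforms
(activations are stationary stochastic processes, not keystroke-locked
bursts), electrode crosstalk, fatigue or nonstationarity within a trial,
amplitude-dependent (multiplicative) envelope noise, and any biomechanics
of the instrument. Passing tests therefore demonstrate that the pipeline
recovers what it is designed to recover under a faithful but simplified
signal model — not that real recordings meet these assumptions.

## Clustering and statistics

Synergies are pooled per body side (sides are clustered in fully
independent runs). k-means (k-means++ initialization, Euclidean distance on
the variance-normalized synergy vectors) is repeated 20 times per k and the
run with the highest mean silhouette kept. The cluster count is the
smallest k whose mutual-assignment percentage — the share of trials with
two or more of their synergies in one cluster — falls below 10%; the
selection is repeated 200 times and the modal k adopted (ties break toward
the smaller k). The final clustering re-runs the best-of-20 k-means at the
modal k.

Inhibitory proportion per synergy is `Σ|w⁻| / Σ|w|` (scale invariant).
Group comparisons use Kruskal–Wallis per (side, cluster), run even with a
singleton group but flagged with a caveat; instance-level records are the
default, with subject-level aggregation as a switch (used for calibration
studies, where pseudo-replication would otherwise inflate the group-test
error rate). Style comparisons pair cells matched on everything except the
contrasted factor (duplicates from mutual assignment are cell-averaged
first), with the sign conventions fast − slow and soft − loud; the
Anderson–Darling normality check is recorded per style but never gates the
Wilcoxon signed-rank test. Component-level modulation tests only channels
whose mean weight is negative in at least one compared style, excludes
clusters with fewer than 10 pairs, drops zero differences
(classical Wilcoxon convention), uses the exact null for n ≤ 25 without
ties and the continuity-corrected normal approximation otherwise. Raw
p-values are reported (thresholds 0.01 for group tests, 0.05 elsewhere);
a Benjamini–Hochberg switch exists and is off by default.

## Benchmark studies (`emgsynergy.evaluation`)

Problem sizes are chosen so each study runs in minutes on one CPU:

* **R² stability**: one 14-channel, 2 000-sample recording at the default
  noise, full 100-NMF/10-best protocol; reports the max pairwise R² spread.
* **Recovery**: 50 noiseless draws (14×800, M = 3); matched cosine of the
  best refined solution against ground truth, and the win rate over the
  best NMF evaluated on the same data.
* **Dimensionality**: an exact-rank-3 envelope built from three
  disjoint-support synergies whose activations are staggered into disjoint
  time thirds — the rows of `C` are then exactly orthogonal with equal
  power, so a rank-2 fit can explain at most 2/3 of the variance at any
  seed; the Eckart–Young bound `σ₃²` re-certifies this (via SVD,
  independently of the factorizer) before the selection rule runs.
* **Clustering**: 120 synthetic trials × 6 synergies drawn from 12
  templates with σ = 0.1 jitter; modal k over 20 selection repetitions and
  the final adjusted Rand index. (120 trials matches the pooled-trial count
  of a realistic session; with far fewer trials the pair-co-occurrence
  estimate underlying MA% becomes too noisy for the 10% rule to resolve
  adjacent k.)
* **Null calibration**: 200 effect-free cohorts (15 subjects, ground-truth
  records); rejection rates of the subject-aggregated Kruskal–Wallis and
  the instance-level paired Wilcoxon at α = 0.05.
* **Planted effects**: 20 reduced cohorts (6 subjects, 2 tasks, one side,
  3 synergies, 8 s trials at 50 Hz; factorization at 8 NMF reps / 3 kept)
  with `proportion_effect = 0.5` on the over-50 group and a +0.08
  less-negative-at-fast shift on the most inhibitory channel of one
  template; the full pipeline runs per cohort and success requires the
  correct cluster, channel and direction. Incidental α-level flags on null
  channels are expected (no multiple-testing correction, matching the
  reporting convention) and are not counted as failures.

## Numerical choices and limitations

* NMF entries are guarded at `1e−12`; NMF/refinement tolerances default to
  `1e−8` relative objective change, 500 iterations.
* Ambiguous column matchings (equal total cosine) break deterministically
  by the lower originating repetition index.
* All sub-seeds derive from a master seed through a stable string path
  (stage → subject → trial → repetition), so adding repetitions never
  perturbs existing streams; derived seeds stay below 2³¹.
* The averaged synergy set refits `C` by nonnegative least squares (the
  alternative — keeping per-repetition activations — leaves `W` and `C`
  inconsistent after averaging).
* Known limitations: the dimensionality rule is sensitive to template
  coherence (highly overlapping synergies let a smaller M clear the 0.8
  threshold); recovery of *minor* negative weights degrades as activation
  duty cycle approaches 1 (identifiability) or as envelope noise grows;
  and the MA% criterion cannot distinguish k from k−1 when the two merged
  templates rarely co-occur within a trial.
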