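# Methods

This note documents the models, statistics and numerical choices behind
`ensdec`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, which
defaults matter, and what the synthetic validation does and does not show.

## Data model

A *session* is a trials table, a long spike-event table and a unit→electrode
map for a 10×10 array. Times are double-precision seconds on a per-trial
clock zeroed at fixation acquisition (the clock origin is a package
convention; nothing downstream depends on it). Every analysis window is a
half-open interval `[start, end)` relative to one of three alignment events
(stimulus onset, color/cue onset, cue offset), so adjacent windows partition
spikes exactly; a spike falling precisely on `end` is excluded. The three
canonical windows are the 500-ms postcue window (0.150–0.650 s after cue
offset), a 500-ms cue window (0–0.5 s after cue onset) and a 700-ms baseline
centered on stimulus onset.

Bundles are three CSV files plus a JSON manifest. Event and spike times are
written with 9 decimal digits, so a round trip preserves times to well under
a microsecond. The bundle stores no recording-duration field, so a window
that extends past the recorded data cannot be detected from the bundle
alone; trials are dropped (with a warning) only when the alignment event
itself is missing. The generator always simulates through the end of the
postcue analysis window.

## Synthetic-session generator

The generator emulates the two-location × two-direction covert attention
task: 353-ms fixation, stimulus onset, a 294/471/647-ms pre-cue interval, a
706-ms color cue, then a postcue period (spikes are simulated until 750 ms
after cue offset). The four location × direction conditions are balanced to
within one trial before outcomes are drawn.

Units are inhomogeneous Poisson processes with piecewise-constant rates:

```
rate_u(t) = baseline_u
            × gain_loc_u(t)   if attended location = preferred and t ≥ cue onset + Δ
            × gain_dir_u(t)   if stimulus direction = preferred and t ≥ stim onset + Δ
            × exp(σ ℓ_u z_t − σ² ℓ_u²/2)
```

- `baseline_u` is log-normal across units (default median 5 Hz, log-SD 0.8,
  a plausible spread for prefrontal units).
- Tuned fractions default to 36% location / 17% direction / 8% both, the
  proportions reported for the more location-selective animal; gains default
  to 1.5 (a moderate attentional/stimulus modulation). Direction gains
  follow the stimulus on every trial; location gains follow the *simulated
  attention state*, which equals the nominal target on hits and sits on the
  distractor with probability `coupling_kappa` (default 0.5) on error
  trials. This single parameter is the smallest mechanism that couples
  decoding accuracy to behavioral outcome.
- `Δ = divergence_onset_s` (default 0.25 s) is when condition-dependent
  rates switch on after the relevant event, giving the latency statistic a
  ground truth.
- The shared per-trial latent `z_t ~ N(0,1)` with unit loadings `ℓ_u` and
  scale `σ = shared_noise_sd` (default 0.2) produces within-condition
  (noise) correlations. The multiplicative log-normal form keeps rates
  positive and the `−σ²ℓ²/2` term makes the gain mean-one, so tuning and
  noise are separable. `loading_mode` controls the correlation geometry:
  `aligned` (all loadings +1) creates a common gain axis that a contrast
  readout can cancel — these correlations *help* a linear decoder of
  mixed-preference ensembles, and removing them lowers accuracy;
  `anti_aligned` ties loading signs to preferred location, putting the noise
  on the signal axis; `random` assigns random signs. No quantitative
  noise-correlation level is available to match, so σ is an explicit
  config parameter, never hard-coded.
- Outcomes (default 75% hit, 5% miss, 15% false alarm, 5% fixation break,
  mirroring a well-trained animal whose errors are mostly false alarms) are
  drawn independently of the spikes except through `coupling_kappa`.
- `cluster_strength` ∈ [0,1] mixes uniform electrode assignment with
  category-specific blocks (location-tuned left half, direction-tuned right
  half); 0 reproduces the spatially unstructured regime, 1 a strongly
  clustered one, so the spatial statistics can be validated in both.

What the generator does **not** emulate: stimulus-onset transients and
epoch-specific rate dynamics (rates are flat apart from tuning gains),
spike-history structure (refractoriness, bursting), low-dimensional shared
dynamics beyond one latent, eye movements, and any dependence of outcome on
the neural state beyond the attention flip. Passing tests therefore certify
the *analysis machinery* — calibration, recovery, exactness — on data that
match the statistical assumptions; they are not evidence about biological
spike trains.

## Selectivity statistics

Task-relatedness: units with overall rate ≤ 0.1 Hz (across the three
canonical windows) are excluded; the rest are flagged when a two-sided
Wilcoxon rank-sum of postcue *or* cue rates against baseline is significant
at α = 0.05.

The two-way ANOVA is computed as an effect-coded OLS fit
(`y ~ 1 + L + D + L·D`, levels ±1), vectorized across units; with one degree
of freedom per term the squared coefficient *t* equals the term's *F*. This
coincides with the classical sum-of-squares ANOVA for balanced designs and
is the Type-III test for the mildly unbalanced designs that arise after
outcome filtering (verified against `statsmodels` `anova_lm(typ=3)` to
machine precision). Counts are analyzed untransformed. The interaction is
estimated but does not enter categorization; a unit with only a significant
interaction is `none`. Zero-variance units report p = 1. The preferred level
of a factor is the one with the higher mean count; d′ is reported signed
toward the preferred level (hence ≥ 0), NaN with fewer than two trials per
level, and ∞ in the degenerate zero-variance/different-means case.

Proportion intervals: both the normal-approximation (Wald,
`z√(p(1−p)/n)`) and Wilson score half-widths are computed. Wald is the
reported default because the reported half-widths (±4.38%, ±3.45%, ±4.8%)
reproduce the Wald formula exactly from the underlying counts (167/462,
80/462, 147/391), although the Wilson interval is named in the source
methods; the discrepancy is documented rather than resolved.

The permutation test permutes the trial-label order (equivalently the trial
order) `n_perm` times, recomputes the ANOVA, takes the mean category
proportions as the null, and compares observed counts with a one-df χ²
goodness-of-fit per category (expected cells clipped below at 0.5). Note a
statistical caveat: the χ² count model assumes independent units. With
shared-gain noise correlations the category counts are overdispersed and the
test rejects more often than its nominal level — a property of applying χ²
to correlated populations, not of this implementation. The calibration tests
therefore run with `shared_noise_sd = 0`.

## Spike density and latency

SDFs are computed on a 1-ms grid by Gaussian smoothing of trial-averaged
histograms. "Kernel width 25 ms" is interpreted as σ = 25 ms (the FWHM
reading would be σ ≈ 10.6 ms); the kernel is truncated at ±4σ with no edge
correction, so traces within ~100 ms of a window edge are biased low (the
kernel-mass unit test quantifies this). Each unit is normalized by the
maximum of its preferred-condition smoothed trace; units with an empty
preferred trace are excluded with a warning.

The latency statistic compares preferred vs nonpreferred mean normalized
activity in 20-ms bins tiling the window from its left edge, with a paired
*t* test across units (the unit of pairing is the cell). Latency is the
start of the first run of ≥5 consecutive significant bins; magnitude is the
mean *t* over all bins. The per-bin means are taken from the *unsmoothed*
normalized responses: the 20-ms bins already provide temporal averaging, and
the non-causal Gaussian kernel would otherwise leak a true divergence
backwards by up to 2–4σ — with ~100 units the paired test is powerful enough
to detect that leakage, biasing latencies ~50–100 ms early. On raw bins the
estimator recovers a 300-ms simulated onset at 0.28–0.30 s. Smoothed-trace
latencies remain available via a flag.

## Spatial statistics

Moran's I with binary weights `w_ij = 1` for `0 < d_ij ≤ scale` (Euclidean,
electrode-pitch units):

```
I = (N/Σw) · Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²
```

Zero variance or an empty neighborhood yields NaN. Because the statistic
needs numeric values, categorical selectivity is encoded as one indicator
map per category; an electrode carrying several units takes the majority
category, ties broken by the most significant unit (smallest main-effect p).
The null band is the central 95% (2.5th–97.5th percentiles) of I under
shuffles of the values across active electrodes — the "95th percentile
range" is read as a central band; the shuffle-null mean matches the
theoretical permutation expectation −1/(N−1).

## Decoding kernel

Trials are balanced by subsampling every location×direction condition to the
minimum per-condition count, repeated `n_balance_repeats` (default 10)
times; each balanced set is split into `n_folds` (default 10) stratified
folds. The classifier is liblinear's L2-regularized squared-hinge linear SVM
(primal, tol 1e-4). The penalty C is selected by a nested stratified
`inner_folds`-fold (default 5) grid search on the training folds only, over
{1e-3…1e3} in decades by default, ties to the smaller C; a one-point grid
skips the search. Accuracy is the fraction of correctly labeled held-out
trials pooled over folds × repeats.

Fold plans (subsample indices plus fold assignments) are first-class,
serializable objects. All candidate evaluations inside one ensemble build
share a single plan, so accuracy differences reflect ensemble composition
rather than resampling noise; this also makes two structural identities
exact rather than statistical: BE and BSU agree at full size, and the BE
pair is at least as accurate as the BSU pair. Every ensemble is additionally
evaluated with its columns in sorted order, so accuracy is a function of the
unit *set* and the size-N identity holds to machine precision.

Chance is obtained by permuting the label rows (class label jointly with
condition label) and re-running the balanced CV with a fresh plan.
Significance against chance uses the tie-inclusive add-one permutation
p-value `p = (1 + #{null ≥ obs}) / (1 + #null)`, which is a valid exact
p-value but cannot fall below `1/(1+#null)`; a one-sided binomial test on
held-out correct counts is provided as an alternative for small null
ensembles. All randomness flows from seeded NumPy generators.

## Ensemble curves and controls

BSU ranks units by single-unit CV accuracy (ties to the smaller unit id) and
adds them in order. BE starts from the best single unit and at each step
keeps the candidate whose addition maximizes ensemble accuracy under the
shared plan (ties to the smaller id); its greedy choices are verified in the
tests against independent exhaustive candidate re-evaluation.

Controls:

- *Label-shuffled (chance) curves* rebuild the memberships on each of
  `n_chance` full label permutations and average. Because each size-k
  membership is argmax-selected, these curves are order statistics and sit
  *above* 0.5 at small sizes even on pure noise (≈0.57 at size 1 with 60
  units and 400 balanced trials) — selection optimism, not leakage. The
  leakage-free calibration property is checked separately: fixed memberships
  evaluated under independently permuted labels are unbiased at 0.5 for
  every size.
- *Decorrelated curves* keep the raw-data membership fixed and recompute
  accuracy on `n_decorr` within-condition shuffles of each unit's trials,
  which preserve every per-unit, per-condition marginal exactly while
  destroying across-unit within-condition correlations. Conditions with one
  trial are left unpermuted. The same selection-optimism caveat applies when
  interpreting raw-minus-decorrelated differences for greedy-selected
  memberships: even with independent units the raw accuracy of an
  argmax-selected ensemble exceeds its reshuffled accuracy by a small margin
  (~+0.03 under the test conditions), so the package's null-effect
  validation uses a fixed ensemble, where the difference is zero in
  distribution.
- Per-size tests: permutation p against the chance rebuilds, and a
  one-sample *t* of the decorrelated accuracies against the raw value (with
  a single session there is no across-session pairing unit; across ≥3
  sessions a paired test across sessions is the intended design).

Curve summaries report the maximum accuracy, the smallest size attaining it,
and the smallest size attaining ≥90% of it; the 90% size may exceed the
argmax size when a single early peak dominates, so no ordering is enforced
between them.

## Behavior-conditioned decoding

Outcome subsets are `all` (hits+misses+false alarms), `hits`, `errors`
(misses ∪ false alarms) and `false_positives` (false alarms). The two large
subsets are scored by stratified CV *without* balancing (error pools are too
small to balance; per-class counts are reported so imbalance is visible).
The small subsets are scored by a classifier trained on all hit trials and
tested on the subset — with tens of error trials, cross-validating within
the subset is not meaningful, and the transfer protocol directly asks
whether the hit-trial code generalizes. Scoring labels are always the
nominal trial condition, never the inferred attention state, so a decoder
tracking the internal state scores at or below chance on fully coupled error
trials. Chance uses 100 label shuffles: full CV recomputation for the CV
subsets, test-label permutation (fixed predictions) for the transfer
subsets.

## Pipeline and reproducibility

`run_all` executes synth → selectivity → dynamics → spatial → ensembles
(both labels) → behavior, each stage writing its own JSON so stages can be
re-run independently; stage seeds derive deterministically from one master
seed via `SeedSequence`. Identical config and seed give byte-identical
bundles and identical reports.

## Problem sizes

The validation suite and the acceptance script run on deliberately small
problems chosen to give stable statistics on a single CPU: sessions of
16–60 units and 240–400 trials for decoding checks (20 seeds where a
criterion is distributional), 100–1000 units for selectivity calibration and
latency recovery, greedy-oracle verification at 6–8 units, and a one-point C
grid with 2–4 balance repeats inside curve builds (the nested grid search is
exercised separately). These sizes are the package's validation conditions;
nothing in the implementation depends on them.

## Known limitations

- The permutation p-value's floor (`1/(1+n_null)`) means ten chance rebuilds
  can never yield p < 0.09; use the binomial alternative or more rebuilds
  when smaller levels are needed.
- Greedy curves are argmax statistics; their small-size accuracies are
  optimistically biased relative to out-of-sample performance, and
  raw-vs-control comparisons at small sizes inherit part of that bias.
- No multiple-comparison correction anywhere (matching the source design).
- The SDF has no edge correction; latency windows should start ≥1 bin before
  the earliest onset of interest and traces near edges are biased low.
- Exhaustive best-subset search is out of scope (combinatorial); the greedy
  builders are heuristics validated per step, not global optima.
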