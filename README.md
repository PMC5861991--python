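# ensdec

Ensemble decoding of covert spatial attention and stimulus motion direction
from multielectrode spike recordings in primate lateral prefrontal cortex
(LPFC, area 8A), together with a fully parameterized synthetic-session
generator so every stage of the analysis can be validated against ground
truth.

The package is aimed at systems neuroscientists analyzing chronically
implanted 10×10 ("Utah") array recordings from a two-alternative covert
attention task: on each trial two random-dot patterns (RDPs) move up or down
left and right of fixation, a transient color cue designates one as the
target, and the subject holds covert attention on the target location
through a sustained *postcue* period. The analyses ask what single units and
simultaneously recorded neuronal ensembles encode about the attended
location and the motion direction during that period, and how that code
relates to behavior.

## What it computes

- **Single-unit selectivity** — task-relatedness screen (Wilcoxon rank-sum
  of cue/postcue rates vs a baseline around stimulus onset, 0.1 Hz rate
  floor), then a two-way ANOVA with factors *target location* ×
  *motion direction* on postcue spike counts. Category proportions get 95%
  confidence half-widths (normal-approximation by default, Wilson score
  available) and a trial-permutation null with per-category χ² tests.
  Effect sizes as d′ = (μ₁ − μ₂)/√((σ₁² + σ₂²)/2).
- **Response dynamics** — normalized spike-density functions (Gaussian
  kernel, σ = 25 ms) and the selectivity latency: the first of ≥5
  consecutive 20-ms bins in which a paired *t* test across units separates
  preferred from nonpreferred responses; magnitude as the mean *t* over all
  bins.
- **Anatomical clustering** — Moran's *I* spatial autocorrelation of
  selectivity over the electrode grid at increasing spatial scales, with a
  95% label-shuffle null band.
- **Population decoding** — an L2-regularized linear SVM (liblinear) decodes
  target location or motion direction from trial spike-count vectors, with
  per-condition trial balancing (×10 subsample repeats), stratified 10-fold
  cross-validation, and a nested grid search for the penalty C.
- **Ensemble building** — two greedy curves of decoding accuracy vs
  ensemble size: **BSU** (add units in order of individual accuracy) and
  **BE** (at each size add the unit that maximizes ensemble accuracy), with
  label-shuffled chance rebuilds, within-condition decorrelation controls
  (destroying noise correlations while preserving marginals), per-size exact
  tests, and summaries (maximum accuracy, size at maximum, size at 90% of
  maximum).
- **Behavior-conditioned decoding** — accuracy of the best ensemble on
  hits, errors, and false alarms separately, with shuffle-based exact tests.

The decoding pieces are scikit-learn compatible (`TunedLinearSVC`,
`GreedyEnsembleSelector` with `fit`/`transform`/fitted attributes).

## Worked example

```python
import numpy as np
from ensdec import (GeneratorConfig, generate_session, extract_counts,
                    POSTCUE_WINDOW, classify_selectivity, DecoderConfig,
                    curve_with_controls, summarize_curve)

cfg = GeneratorConfig(n_units=40, n_trials=300, gain_location=2.0,
                      gain_direction=2.0, seed=7)
session, truth = generate_session(cfg)
counts = extract_counts(session, POSTCUE_WINDOW)   # hits only, 500-ms window

sel = classify_selectivity(counts, alpha=0.05)
print("category counts:", sel.category.value_counts().to_dict())
print("true counts:    ", truth.category_counts())

dec = DecoderConfig(label="target_location", c_grid=(1.0,),
                    n_balance_repeats=2, seed=1)
res = curve_with_controls(counts.counts, counts.binary_labels("target_location"),
                          dec, counts.condition_labels(), n_decorr=10,
                          n_chance=3, unit_ids=counts.unit_ids, max_size=10)
be = res["curves"][("BE", "raw")]
print("BE accuracy per size:", np.round(be.accuracy_per_size, 3))
s = summarize_curve(be)
print(f"BE max {s.max_accuracy:.3f} at size {s.size_at_max}; "
      f"90% of max at size {s.size_at_90pct_of_max}")
```

Output:

```
category counts: {'none': 16, 'location': 14, 'direction': 7, 'both': 3}
true counts:     {'location': 14, 'direction': 7, 'both': 3, 'none': 16}
BE accuracy per size: [0.852 0.964 0.984 0.989 0.995 1.  1.  1.  1.  1. ]
BE max 1.000 at size 6; 90% of max at size 2
```

The ANOVA recovers the generator's tuned fractions exactly here (14
location-, 7 direction-, 3 both-tuned of 40 units), and the best-ensemble
curve shows the signature the method is built to expose: the best single
unit decodes the attended location at 85%, a greedy pair at 96%, and a
six-unit ensemble is perfect, after which the curve saturates — small
ensembles carry essentially all the decodable information.

A command-line interface mirrors the library
(`ensdec synth | selectivity | dynamics | clustering | decode | ensembles |
behavior | run`); `ensdec run --config run.yaml` executes the full pipeline
on a bundle and writes JSON reports with full seed provenance.

## Layout

```
src/ensdec/
  io.py          session bundles, epoch windows, spike-count extraction
  synth.py       synthetic-session generator with ground truth
  selectivity.py rank-sum screen, 2x2 ANOVA, d', proportion permutation test
  dynamics.py    spike-density functions, consecutive-bin latency
  spatial.py     Moran's I clustering profiles over the array
  decoder.py     balanced CV linear-SVM kernel, fold plans, exact tests
  ensembles.py   BSU/BE curves, decorrelation, chance rebuilds, summaries
  behavior.py    outcome-conditioned decoding
  pipeline.py    one-command orchestration
  cli.py         click CLI
```

See `docs/methods.md` for the statistical and modeling details.
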