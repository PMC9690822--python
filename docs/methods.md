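# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `dietrec`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Rating construction

The preference signal is the within-consumer quantile of intake. For each
food group independently, `QuintileRatingTransformer.fit` records the
positive intake values of the fitting sample (that group's *consumers*;
zeros are excluded because non-consumption is defined as the
recommendation candidate set, not as a low preference). `transform` maps
an intake `x > 0` to its mid-rank `r` among the fitted consumer values
(`r = #{v < x} + (#{v = x} + 1)/2`), converts to a quantile position
`p = (r − 0.5)/n`, and bins at 0.2/0.4/0.6/0.8 into ratings 1–5.

Consequences of this rule, all under test:

* ratings are deterministic and exchangeable — tied intakes always share
  a rating;
* a lone consumer sits at `p = 0.5` and rates 3;
* with `n` distinct consumers each rating class receives `⌊n/5⌋` or
  `⌈n/5⌉` of them;
* values outside the fitted range clamp to ratings 1/5, so test users are
  rated on the *training* distribution with no leakage. The alternative —
  fitting quintiles on the pooled sample before splitting — is expressible
  but not used by the pipeline entry points.

Groups with no consumers yield an all-missing column (with a warning);
groups with fewer than 5 distinct positive values degenerate gracefully
to the tie rule (warning).

## Similarity

Pairwise Pearson correlation over co-observed cells, computed for all
pairs at once from masked sum matrices. A pair is undefined (NaN) when
the overlap is below `min_overlap` (default 3) or either side is constant
on the overlap; the variance term `n·Σx² − (Σx)²` is integral for integer
ratings, so an absolute cutoff of 1e-6 cleanly separates true zeros from
matmul round-off. The diagonal is 1 for any entity with at least one
rating. `pearson_cross` computes the same statistic between the rows of
two matrices sharing an item axis, which is how new users are related to
a fitted user base.

## Collaborative filtering

* **UBCF** (default `k_neighbors = 25`): mean-centered weighted
  aggregation over the k most similar users who rated the item. Centering
  corrects inter-user rating-scale bias and is the standard k-NN
  formulation.
* **IBCF** (default `k_neighbors = 30`): uncentered similarity-weighted
  average of the user's own ratings on the k most similar items. With 21
  items, the default k effectively means "all usable similar items".
* `positive_only = True` by default: aggregating ratings with negative
  weights is ill-behaved on a bounded 1–5 scale. Switchable.
* Ties in similarity break toward the lower index; prediction contains no
  randomness.
* Predictions clamp to [1, 5]. A cell whose neighborhood is empty or
  whose absolute-similarity sum is zero is `unpredictable`: excluded from
  error metrics (with a reported count) but still penalized as
  not-recommended in retrieval metrics, so abstention is not free.

Defaults for `k` and `min_overlap` follow common collaborative-filtering
practice; both are constructor arguments and CLI flags.

## Evaluation protocol

Users are split 70/30 at random. Each test user keeps exactly
`given = 10` observed ratings visible; the remainder are withheld as
truth. Models are **fitted on the training users only** and predict the
test users' missing cells from their visible rows. This matters for
UBCF: if the sparse 10-item test rows are instead pooled into the fitted
matrix, pairs of test users co-rate only ~4–5 items and produce spurious
perfect correlations that crowd genuine neighbors out of the top-k (we
measured neighbor archetype purity dropping to 0.57 and the RMSE
advantage over baseline vanishing). Restricting the neighbor pool to the
densely rated training base avoids the pathology and mirrors how the
recommender would serve a new patient.

Scoring:

* **Rating error** — RMSE/MSE/MAE over (estimate, withheld truth) pairs,
  via scikit-learn metrics, against a global-mean baseline (predict the
  grand mean of all visible ratings).
* **Top-N retrieval** — recommendation lists of lengths {1, 3, 5, 10}
  are scored per user against the withheld items: relevant = withheld
  with rating ≥ `good_rating` (default 1, i.e. any consumption counts);
  TP/FP/FN/TN partition the user's candidate universe (all items minus
  the 10 visible ones, hence always 11 under the defaults). Rates derive
  from the per-user *mean* counts — precision = TP̄/(TP̄+FP̄) etc. — which
  is the arithmetic printed in published confusion tables of this style.
  The (FPR, TPR) and (recall, precision) points traced across list sizes
  are the ROC and precision–recall curves.
* Evaluation mode scores all 21 groups (`eligible_only = False`): a
  candidate pool capped at the 8 eligible groups could not produce mean
  TP values above 8, contradicting the published top-10 rows this
  protocol mirrors. Production recommendation mode applies the
  eligibility constraint.

A zero denominator in any rate yields 0 by convention. Recommending a
visible item is a protocol violation and raises. Test users with ≤ 10
observed ratings cannot donate a withheld set and are dropped with a
warning.

## Synthetic cohort generator

Real FFQ cohorts of this kind are not redistributable, so the generator
emulates their statistical shape:

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_participants` | 2000 | — | large enough for stable 70/30 + given-10 evaluation, small enough for seconds-scale runs |
| groups | 21 | — | the catalog's food-group universe |
| `sigma_log` | 0.55 | log-grams | within-archetype spread; ~60% coefficient of variation, typical of usual-intake estimates |
| archetype shift | ±0.9 | log-grams | marker-food contrast exp(0.9) ≈ 2.5× between patterns, as seen between extreme dietary-pattern quintiles |
| `p_zero` | ~0.01 background + 0.10–0.30 on pattern-specific groups | probability | ≈ 1 non-consumed group per participant, concentrated in a minority of groups |
| archetype weights | 0.40 / 0.35 / 0.25 | — | prudent / western / mixed |
| `kcal_per_gram` | 0.8 | kcal/g | whole-diet energy density (solids ~1.5–2 kcal/g diluted by beverages), putting median energy near 2300 kcal/day |
| `energy_noise_sd` | 150 | kcal/day | reporting/metabolic noise |
| `implausible_fraction` | 0.16 | — | share of rows forced outside the [500, 4000] kcal plausibility window for the exclusion step to catch |

Three archetypes plant the collaborative-filtering signal: "prudent"
shifts the 8 guideline-aligned groups up and the western marker groups
down, "western" the reverse, "mixed" sits at the baseline; each also has
its own non-consumption profile (e.g. prudent participants tend not to
drink soft drinks, western participants tend not to eat whole cereals or
oilseeds). Ground-truth labels are emitted so recovery checks are
assertable. `null_config()` provides the calibration null: one archetype,
i.i.d. participants, no planted correlation.

What the generator does **not** emulate: item-level FFQ structure (a
small synthetic item→group mapping exists only to test collapsing),
demographic or clinical confounding, within-archetype correlation beyond
the shared location shifts, seasonal or secular intake variation, and
measurement error specific to FFQ instruments. Passing recovery tests
therefore show that the pipeline recovers *planted correlation structure
of this form* — not that any particular real cohort carries such
structure; no claim is made that the archetypes reproduce real dietary
patterns.

## Problem sizes and reproducibility

The planted-recovery study uses 20 cohorts of 2,000 participants (plus 5
null cohorts) — sizes chosen to make the 20-seed median RMSE improvement
and the null calibration stable at seconds-per-cohort cost. Every
stochastic stage takes an explicit seed; the CLI derives per-stage
substreams from one top-level `--seed`, and identical configuration plus
seed reproduces evaluation reports byte-for-byte.

## Known limitations

* With 21 items, quintile ratings are coarse; CF lift is bounded by the
  archetype-conditional rating spread (on the default synthetic cohort
  the archetype-aware oracle reaches ~13–20% RMSE improvement, and UBCF
  recovers most of it).
* The random-ranking precision base rate is high (~0.9) because nearly
  all withheld candidates are consumed items under near-complete
  coverage; precision differences between methods are correspondingly
  small, exactly as in the published tables this protocol mirrors.
* IBCF's uncentered average cannot correct user-level rating bias; it is
  kept in its standard form deliberately.
* Single 70/30 split by design; no cross-validation or significance
  testing across methods.
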