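# Methods

## Setting

A ranking method reduces each feature of a high-throughput experiment
(gene, metabolite, genomic window …) to a scalar score, and the truth —
which features are real positives — is known, as in spike-in benchmarks.
The evaluation question is how well the scores separate the two classes
when the true negative class is much larger than the true positive class.
Throughout, the *class ratio* means #negatives / #positives.

## Curve construction

Scores are first **oriented**: if the positive-class median lies left of
the negative-class median, every score is negated, so "high score" always
means "called positive". A median tie causes no flip; the operation is
idempotent.

Sweeping a cutoff δ over the distinct score values in decreasing order,
the discovery set at point k is `{score ≥ δ_k}`. Tied scores enter or
leave as one block, which keeps the realized FDR = FP/(TP+FP) well
defined at every stored point (each has ≥ 1 discovery). The empty
discovery set is not an operating point — its FDR would be 0/0. The
conceptual (FPR, TPR) = (0, 0) origin is supplied by the integration
convention below, not stored.

## Metrics

All metrics are rectangle (step-function) sums; the empirical curves are
step functions, so no trapezoidal smoothing is applied. With
ΔTPR_k = tpr_k − tpr_{k−1} (tpr_{−1} := 0):

| quantity | definition | range |
|---|---|---|
| AUC | Σ ΔTPR_k (1 − FPR_k) | [0, 1] |
| VUS | Σ ΔTPR_k · TDR_k · (1 − FPR_k) | [0, VUS ≤ AUC] |
| FCAUC(b) | AUC of the curve capped at t\* = TPR(δ\*) | [0, AUC] |

where δ\* is the **most liberal** (smallest) cutoff with FDR(δ\*) ≤ b.
The empirical FDR need not be monotone in δ, so the selection scans all
cutoffs rather than bisecting. If no cutoff is admissible, FCAUC = 0;
FCAUC(1) = AUC exactly.

Numerical conventions worth knowing:

- Within a tied block, the whole ΔTPR is credited at the block's endpoint
  FPR and TDR — the conservative choice. A consequence: a fully tied
  score vector has a single operating point at (FPR, TPR) = (1, 1), so
  its AUC is 0 under this convention where a trapezoidal rule would give
  0.5. For tie-free scores the AUC equals the Mann–Whitney concordance
  fraction exactly.
- FCAUC is the area under the ROC curve **capped at height t\***, not the
  partial area left of FPR(δ\*). Only the cap reading gives FCAUC ≈ 1 for
  well-separated classes, where FPR(δ\*) = 0 would zero out a
  left-partial area. When the δ\* block itself straddles the admissible
  level mid-block, the block-endpoint rule above decides; ties are never
  split.
- VUS = AUC whenever TDR ≡ 1, and VUS = c·AUC for constant TDR ≡ c (this
  identity is property-tested).

Because TDR depends on the class composition of the discovery set, VUS
and FCAUC change under label swapping even when AUC does not: the two
class labels are not exchangeable, by design.

## Significance tests

**Single surface (permutation).** Truth labels are shuffled against the
fixed scores K times; orientation is re-applied to each permuted dataset
(a relabeling can flip the median order). The one-sided p-value is the
plain exceedance proportion `#{null ≥ observed} / K`. The (k+1)/(K+1)
correction, which keeps p strictly positive, is available via
`plus_one=True` but off by default so the reported value is the plain
proportion. With the plain rule, degenerate inputs behave sensibly:
all-tied scores give p = 1.

**Two surfaces (bootstrap).** Null hypothesis: the two studies share the
same class-specific distributions of ranks. The statistic is
|VUS₁ − VUS₂| on the full original (oriented) studies. The null
distribution is built by (i) resampling, from each study,
(n₀+m₀)/2 negatives and (n₁+m₁)/2 positives (nearest-integer rounding;
with replacement, which is required whenever the target exceeds a
study's own count and is used uniformly for simplicity) — this removes
the influence of unequal class ratios; (ii) rank-transforming within
study, ties broken uniformly at random; (iii) pooling negative ranks and
positive ranks across studies; (iv) drawing B replicate study pairs at
the original sizes (n₁/n₀ and m₁/m₀) with replacement from the pools;
(v) exceedance proportion as above. Each bootstrap replica is oriented
before its VUS is computed, matching what would be done with real data;
under the null the pools are exchangeable so this does not bias the
statistic's distribution. VUS is rank-invariant for tie-free scores, so
the rank transform in (ii) does not alter the statistic being studied;
for heavily tied data the random tie-breaking injects the corresponding
uncertainty into the null. B ≥ 199 is recommended for α = 0.05.

With identical input studies the observed difference is 0 and the ≥
exceedance rule gives p = 1, as it should.

All randomness flows from one integer seed through a
`numpy.random.Generator`; every `TestResult` records its seed, null
sample and resample count.

## Synthetic data

The generator draws both classes from normal distributions with shared
standard deviation 1 — negatives N(0, 1), positives N(d, 1) for a chosen
separation d — because this two-parameter family (separation d, class
ratio r) spans the phenomena the metrics are designed to expose, from
perfect separation to complete overlap at extreme skew. A total sample
size is split by the class ratio as n_pos = round(n/(1+r)) (minimum 1),
n_neg = n − n_pos.

Two experiment drivers:

- `vus_fcauc_grid`: mean VUS and FCAUC over a (d × r) grid; defaults
  d ∈ {0, 0.5, …, 6}, r ∈ {1, 2, 4, 8, 16}, 50 replicates of 2000
  samples per cell, FDR level b = 0.2 (the package-wide default).
- `size_power_experiment`: empirical rejection rate of the two-surface
  test over replicate study pairs; with equal positive-class means it
  measures the size of the test, otherwise its power.

What the simulations do **not** emulate: correlated features (scores on
real features are rarely independent), non-Gaussian and heteroscedastic
score distributions, and estimated (rather than known) truth labels.
Passing tests therefore certify the algebra and the calibration of the
tests under an idealized design, not performance on any particular real
dataset.

Problem sizes: the full-scale size study (study pairs of 4000 samples,
B = 199, 100 replicates) runs in the acceptance check; the unit-level
calibration tests use scaled-down versions (hundreds of samples, B = 99,
60 replicates) with correspondingly generous binomial envelopes, chosen
so the whole suite stays interactive while still detecting a
miscalibrated test.

## Design choices in open territory

- **AUC is computed with the same step convention as VUS** rather than
  delegated to a generic ROC library, so that AUC, VUS and FCAUC are
  mutually consistent on tied data; the independent cross-check in the
  tests is brute-force concordance counting, and VUS is checked against
  a fine-grid numeric integration oracle.
- **read_curve** (user-supplied FPR/TPR/FDR tables) synthesizes
  thresholds as the descending row index, sorts rows to non-decreasing
  TPR (stable), and leaves the class counts unset — they are unknowable
  from rates alone. Round-tripping a computed curve through CSV
  preserves AUC/VUS/FCAUC to 1e-12.
- **Plots are static** (PNG/SVG via matplotlib): a ruled surface
  spanning, at each TPR level, FPR from the curve to 1 at height TDR,
  with the floor projection shaded; and a 2D ROC with segments
  dichotomized at FDR ≤ b and the FDR-controlled area shaded, the FCAUC
  printed in the legend. Interactive rotatable rendering is a non-goal.
- **Rounding** of the (n₀+m₀)/2 resample targets uses floor(x + 0.5)
  (round-half-up) to avoid banker's-rounding surprises.

## Limitations

- VUS and FCAUC inherit the class ratio of the evaluation data; they
  transfer to future data only if the ratio is comparable. Re-evaluate
  after resampling to a target ratio if not.
- The FDR here is the *realized* false-discovery proportion under known
  truth labels (spike-in style), not an estimated FDR from a
  multiple-testing procedure.
- p-values are plain exceedance proportions and can be exactly 0 at
  finite K/B; use `plus_one=True` where a strictly positive p-value is
  required.
- Only comparisons of two studies are supported; correction across many
  pairwise comparisons is left to the caller.
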