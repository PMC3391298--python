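# rocsurface

Evaluation of rankers and classifiers on **heavily class-skewed** labeled
data — the situation, common in high-throughput biology, where true
negatives outnumber true positives by one or two orders of magnitude
(spike-in benchmarks, copy-number break-point detection, any screen where
only the top of a ranking is acted upon).

On such data the ordinary ROC curve and its AUC are misleading: almost the
entire curve corresponds to cutoffs at which the false discovery rate (FDR)
is unacceptably high, so two methods with similar AUC can differ wildly in
the only region a practitioner uses. `rocsurface` lifts the ROC curve into
a **surface** over the FPR–TPR plane whose height is the true discovery
rate, TDR = 1 − FDR, and summarizes it with quantities that respond to both
class separation *and* class ratio.

## The statistics

For a score threshold δ swept from high to low (positives oriented to the
right), each distinct score value gives an operating point with
TPR(δ) = TP/#pos, FPR(δ) = FP/#neg, FDR(δ) = FP/(TP+FP), TDR = 1 − FDR.
The empirical curves are step functions, so integrals become sums over the
TPR increments ΔTPR_k:

- **AUC** = Σ_k ΔTPR_k · (1 − FPR_k) — the usual area under the ROC curve
  (the Mann–Whitney concordance fraction for tie-free scores);
- **VUS** (volume under the ROC surface) = Σ_k ΔTPR_k · TDR_k · (1 − FPR_k)
  — a TDR-weighted AUC. It is 1 exactly under perfect separation at *any*
  class ratio, and falls toward 0 for inseparable classes as the
  negative:positive ratio grows;
- **FCAUC(b)** (FDR-controlled AUC) — the area under the ROC curve
  restricted to operating points with FDR ≤ b: the curve is capped at the
  TPR of the most liberal admissible cutoff. If no cutoff achieves FDR ≤ b,
  the FCAUC is 0.

Because VUS and FCAUC depend on the class ratio, positive and negative
labels are **not** exchangeable, and the values are meaningful only when
the class ratio of the evaluation data resembles that of future data.

Two significance procedures are included: a label-permutation test for a
single surface (is the separation better than chance, measured by VUS or
FCAUC?), and a bootstrap test for the **difference between two surfaces**
(statistic |VUS₁ − VUS₂|) that first equalizes class-ratio influence by
resampling and pools within-study ranks to build the null. A two-class
Gaussian simulator reproduces the separation × class-ratio grid and the
size/power experiments used to characterize these tests.

## Worked example

Six scored features, three spiked-in positives (`label` 1) and three
negatives:

```sh
$ cat demo.csv
score,label
0.9,1
0.8,1
0.7,0
0.6,0
0.5,1
0.4,0

$ rocsurface curve demo.csv -o demo_curve.csv
n_points	6
n_pos	3
n_neg	3

$ cat demo_curve.csv
threshold,fpr,tpr,fdr,tdr
0.9,0.0,0.3333333333333333,0.0,1.0
0.8,0.0,0.6666666666666666,0.0,1.0
0.7,0.3333333333333333,0.6666666666666666,0.3333333333333333,0.6666666666666667
0.6,0.6666666666666666,0.6666666666666666,0.5,0.5
0.5,0.6666666666666666,1.0,0.4,0.6
0.4,1.0,1.0,0.5,0.5

$ rocsurface auc demo.csv
auc	0.7777777777777778

$ rocsurface vus demo.csv
vus	0.7333333333333333

$ rocsurface fcauc demo.csv --fdr 0.2
fcauc	0.6666666666666666
```

Reading the numbers: the AUC is 7/9 — of the nine positive–negative score
pairs, seven are correctly ordered. The VUS is lower (11/15) because the
TPR step from 2/3 to 1 is only reached at FDR = 0.4, so it is down-weighted
by its TDR of 0.6. At an acceptable FDR of 0.2 only the first two cutoffs
qualify, capping the usable part of the curve at TPR = 2/3, hence
FCAUC = 2/3.

The same quantities are available from Python:

```python
from rocsurface import LabeledScores, compute_curve, orient, vus

curve = compute_curve(orient(LabeledScores([0.9, 0.8, 0.7, 0.6, 0.5, 0.4],
                                           [1, 1, 0, 0, 1, 0])))
vus(curve)  # 0.7333333333333333
```

Other subcommands: `permtest` (label-permutation test), `compare`
(two-surface bootstrap test), `simulate-grid` / `simulate-power`
(Gaussian experiments), `plot3d` (static 3D surface) and `plotroc` (ROC
colored by FDR ≤ b with the FDR-controlled area shaded). All results are
printed as `name<TAB>value` lines; every resampling command takes and
echoes a `--seed`.

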