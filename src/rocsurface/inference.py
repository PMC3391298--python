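"""Significance tests for ROC-surface metrics.

Two resampling tests are provided:

* :func:`permutation_test` — is the observed class separation (as VUS or
  FCAUC) larger than chance? The null distribution is built by shuffling
  the truth labels against the fixed scores.
* :func:`two_rocs_test` — do two studies share the same class-specific
  rank distributions? A bootstrap test on the absolute VUS difference,
  with a resampling step that equalizes the influence of differing class
  ratios before pooling within-study ranks into null distributions.

Both report the plain exceedance proportion ``#{null >= observed} / K``
as the one-sided p-value. The optional ``plus_one`` flag applies the
(k+1)/(K+1) finite-sample correction, which guarantees a strictly
positive p-value; it is off by default to match the plain proportion
definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import LabeledScores, ValidationError, compute_curve, orient, rank_transform
from . import metrics

__all__ = ["TestResult", "TwoStudies", "permutation_test", "two_rocs_test"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a resampling test.

    ``p_value`` is the exceedance proportion of ``null_values`` over
    ``observed`` (with the optional add-one correction noted in
    ``corrected``); ``seed`` records the generator seed so any result can
    be reproduced exactly.
    """

    observed: float
    null_values: np.ndarray
    p_value: float
    n_resamples: int
    seed: int
    statistic: str
    corrected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "null_values", np.asarray(self.null_values, dtype=float)
        )
        if self.null_values.shape != (self.n_resamples,):
            raise ValidationError("null sample count differs from n_resamples")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


@dataclass(frozen=True)
class TwoStudies:
    """A pair of scored, labeled studies to be compared."""

    study1: LabeledScores
    study2: LabeledScores


def _p_value(null_values: np.ndarray, observed: float, plus_one: bool) -> float:
    exceed = int(np.sum(null_values >= observed))
    if plus_one:
        return (exceed + 1) / (null_values.size + 1)
    return exceed / null_values.size


def permutation_test(
    data: LabeledScores,
    statistic: str = "vus",
    K: int = 1000,
    b: float = 0.2,
    seed: int = 0,
    plus_one: bool = False,
) -> TestResult:
    """Label-permutation test of class separation.

    The observed statistic (``"vus"`` or ``"fcauc"``, the latter at FDR
    level ``b``) is compared with ``K`` recomputations under random
    relabelings of the features, scores held fixed. Orientation is
    re-applied to every permuted dataset, since a relabeling can flip
    which class has the higher median. One-sided: large statistics are
    evidence of separation.
    """
    if K < 1:
        raise ValidationError("K must be a positive integer")
    if statistic not in ("vus", "fcauc"):
        raise ValidationError(f"unknown statistic {statistic!r}")

    def evaluate(d: LabeledScores) -> float:
        curve = compute_curve(orient(d))
        if statistic == "vus":
            return metrics.vus(curve)
        return metrics.fcauc(curve, b)

    observed = evaluate(data)
    rng = np.random.default_rng(seed)
    null_values = np.empty(K)
    for k in range(K):
        permuted = LabeledScores(data.scores, rng.permutation(data.labels))
        null_values[k] = evaluate(permuted)
    return TestResult(
        observed=observed,
        null_values=null_values,
        p_value=_p_value(null_values, observed, plus_one),
        n_resamples=K,
        seed=seed,
        statistic=statistic,
        corrected=plus_one,
    )


def _oriented_vus(pos: np.ndarray, neg: np.ndarray) -> float:
    scores = np.concatenate([neg, pos])
    labels = np.r_[np.zeros(neg.size, bool), np.ones(pos.size, bool)]
    return metrics.vus(compute_curve(orient(LabeledScores(scores, labels))))


def two_rocs_test(
    studies: TwoStudies,
    B: int = 199,
    seed: int = 0,
    plus_one: bool = False,
) -> TestResult:
    """Bootstrap test for a difference between two ROC surfaces.

    Null hypothesis: the two studies are generated from the same
    class-specific distributions of ranks. The statistic is the absolute
    VUS difference ``|VUS1 - VUS2|`` computed on the full original
    (oriented) studies. The null distribution is built as follows:

    1. From each study, resample (with replacement) ``(n0 + m0) / 2``
       negatives and ``(n1 + m1) / 2`` positives (rounded to nearest),
       removing the influence of unequal class ratios.
    2. Rank-transform the resampled values within each study, breaking
       ties at random.
    3. Pool the negative ranks of both studies into one null negative
       distribution, and likewise the positive ranks.
    4. For each of ``B`` replicates, draw with replacement a study-1
       replica (``n1`` positives, ``n0`` negatives) and a study-2 replica
       (``m1`` positives, ``m0`` negatives) from the pools and record
       ``|VUS1 - VUS2|``.
    5. p-value = exceedance proportion of the null sample over the
       observed difference.
    """
    if B < 1:
        raise ValidationError("B must be a positive integer")
    s1 = orient(studies.study1)
    s2 = orient(studies.study2)

    observed = abs(
        metrics.vus(compute_curve(s1)) - metrics.vus(compute_curve(s2))
    )

    n1, n0 = s1.n_pos, s1.n_neg
    m1, m0 = s2.n_pos, s2.n_neg
    half_neg = int(np.floor((n0 + m0) / 2 + 0.5))
    half_pos = int(np.floor((n1 + m1) / 2 + 0.5))

    rng = np.random.default_rng(seed)
    pos_pool, neg_pool = [], []
    for study in (s1, s2):
        pos = rng.choice(study.positive_scores, size=half_pos, replace=True)
        neg = rng.choice(study.negative_scores, size=half_neg, replace=True)
        ranks = rank_transform(np.concatenate([neg, pos]), rng)
        neg_pool.append(ranks[:half_neg])
        pos_pool.append(ranks[half_neg:])
    pos_pool = np.concatenate(pos_pool).astype(float)
    neg_pool = np.concatenate(neg_pool).astype(float)

    null_values = np.empty(B)
    for k in range(B):
        v1 = _oriented_vus(
            rng.choice(pos_pool, size=n1, replace=True),
            rng.choice(neg_pool, size=n0, replace=True),
        )
        v2 = _oriented_vus(
            rng.choice(pos_pool, size=m1, replace=True),
            rng.choice(neg_pool, size=m0, replace=True),
        )
        null_values[k] = abs(v1 - v2)

    return TestResult(
        observed=observed,
        null_values=null_values,
        p_value=_p_value(null_values, observed, plus_one),
        n_resamples=B,
        seed=seed,
        statistic="abs_vus_difference",
        corrected=plus_one,
    )
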