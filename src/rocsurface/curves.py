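"""Operating-point curves for class-skewed classifier evaluation.

A scored, binary-labeled feature set is turned into an ordered sequence of
operating points. Sweeping a score threshold :math:`\\delta` from high to
low, each point records the true positive rate (TPR), false positive rate
(FPR), false discovery rate (FDR) and true discovery rate (TDR = 1 - FDR)
of the discovery set ``{score >= delta}``. All downstream metrics (AUC,
volume under the ROC surface, FDR-controlled AUC) and significance tests
consume this curve.

Conventions
-----------
* Scores are oriented so the true positive class sits to the right
  (higher scores); :func:`orient` negates scores when the positive-class
  median is left of the negative-class median.
* Tied scores enter or leave the discovery set as one block, so every
  operating point corresponds to a distinct score value.
* The empty discovery set is not an operating point (its FDR would be
  0/0); curves start at the first non-empty cutoff. The conceptual
  (FPR, TPR) = (0, 0) origin is supplied by the integration convention
  in :mod:`rocsurface.metrics`, not stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "LabeledScores",
    "RocsCurve",
    "orient",
    "compute_curve",
    "rank_transform",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class LabeledScores:
    """Per-feature scalar scores with binary truth labels.

    Parameters
    ----------
    scores
        Unitless ranking scores, one per feature.
    labels
        Boolean truth labels of the same length; ``True`` marks the true
        positive class. Alternatively any array coercible to bool.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValidationError("scores and labels must be one-dimensional")
        if scores.shape[0] != labels.shape[0]:
            raise ValidationError(
                f"length mismatch: {scores.shape[0]} scores vs "
                f"{labels.shape[0]} labels"
            )
        if scores.shape[0] < 2:
            raise ValidationError("need at least two scored features")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite")
        if labels.all() or not labels.any():
            raise ValidationError(
                "single-class input: need at least one positive and one "
                "negative label"
            )

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @property
    def positive_scores(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def negative_scores(self) -> np.ndarray:
        return self.scores[~self.labels]


@dataclass(frozen=True)
class RocsCurve:
    """Ordered operating points of a score threshold sweep.

    ``thresholds`` is strictly decreasing with one entry per distinct
    score; arrays ``fpr``, ``tpr``, ``fdr``, ``tdr`` share its length.
    ``n_pos``/``n_neg`` are the class counts behind the rates; they are
    ``None`` for curves read from user-supplied rate tables, where the
    counts are unknown.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    fdr: np.ndarray
    n_pos: int | None = None
    n_neg: int | None = None
    tdr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("thresholds", "fpr", "tpr", "fdr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "tdr", 1.0 - self.fdr)
        n = self.thresholds.shape[0]
        if n == 0:
            raise ValidationError("curve has no operating points")
        for name in ("fpr", "tpr", "fdr"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValidationError(f"{name} length differs from thresholds")
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                bad = np.nonzero((arr < -1e-12) | (arr > 1 + 1e-12))[0]
                raise ValidationError(
                    f"{name} outside [0, 1] at rows {bad.tolist()}"
                )
        if np.any(np.diff(self.thresholds) >= 0):
            raise ValidationError("thresholds must be strictly decreasing")
        if np.any(np.diff(self.fpr) < -1e-12) or np.any(np.diff(self.tpr) < -1e-12):
            raise ValidationError("fpr and tpr must be non-decreasing")

    def __len__(self) -> int:
        return int(self.thresholds.shape[0])


def orient(data: LabeledScores) -> LabeledScores:
    """Orient scores so the positive-class median is right of the negative.

    Returns ``data`` unchanged when ``median(positives) >=
    median(negatives)`` (ties included); otherwise returns a copy with
    every score negated. Labels are never touched, so the operation is
    idempotent.
    """
    if np.median(data.positive_scores) >= np.median(data.negative_scores):
        return data
    return LabeledScores(-data.scores, data.labels)


def compute_curve(data: LabeledScores) -> RocsCurve:
    """Sweep all distinct score cutoffs and return the operating-point curve.

    The input must already be oriented (positives to the right). Point
    ``k`` treats every feature with ``score >= thresholds[k]`` as a
    discovery; tied scores move as one block. Rates:

    * ``tpr = TP / n_pos``, ``fpr = FP / n_neg``
    * ``fdr = FP / (TP + FP)`` — the realized false-discovery proportion,
      well defined because every stored cutoff has at least one discovery
    * ``tdr = 1 - fdr``
    """
    order = np.argsort(-data.scores, kind="stable")
    sorted_scores = data.scores[order]
    sorted_pos = data.labels[order]

    # last index of each tied block in descending-score order
    block_end = np.r_[np.diff(sorted_scores) != 0, True]
    n_discoveries = np.flatnonzero(block_end) + 1.0
    tp = np.cumsum(sorted_pos)[block_end].astype(float)
    fp = n_discoveries - tp

    return RocsCurve(
        thresholds=sorted_scores[block_end],
        fpr=fp / data.n_neg,
        tpr=tp / data.n_pos,
        fdr=fp / n_discoveries,
        n_pos=data.n_pos,
        n_neg=data.n_neg,
    )


def rank_transform(
    scores: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Rank scores 1..n, breaking ties uniformly at random.

    Each tied block receives a random permutation of its rank range, so
    every ordering consistent with the scores is equally likely. The
    result is deterministic for a given ``seed`` (an integer or an
    existing :class:`numpy.random.Generator`).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.shape[0] < 1:
        raise ValidationError("scores must be a non-empty 1-D sequence")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tiebreak = rng.random(scores.shape[0])
    order = np.lexsort((tiebreak, scores))
    ranks = np.empty(scores.shape[0], dtype=np.int64)
    ranks[order] = np.arange(1, scores.shape[0] + 1)
    return ranks
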