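"""Summary metrics of an operating-point curve: AUC, VUS and FCAUC.

All three are step-function (rectangle) sums over the empirical curve —
the curve is a step function, so integrals are replaced by summations.
With ``dTPR[k] = tpr[k] - tpr[k-1]`` (and ``tpr[-1] := 0``):

* ``AUC  = sum_k dTPR[k] * (1 - fpr[k])`` — the area under the ROC curve,
  integrating over TPR levels; equal to the Mann-Whitney concordance
  fraction for tie-free scores.
* ``VUS  = sum_k dTPR[k] * tdr[k] * (1 - fpr[k])`` — the volume under the
  ROC surface, a TDR-weighted AUC. It reaches 1 only under perfect
  separation (any class ratio) and tends to 0 for inseparable classes as
  the negative:positive ratio grows.
* ``FCAUC(b)`` — the area under the ROC curve restricted to operating
  points with realized FDR at or below the acceptable level ``b``: the
  curve is capped at the TPR of the most liberal cutoff satisfying
  ``FDR <= b`` and the step sum re-evaluated.

Each TPR step is credited at the FPR/TDR of the tied block's endpoint,
which is the conservative choice for blockwise ties. A consequence worth
noting: a fully tied score vector yields a single step achieved at
FPR = 1, so its AUC is 0 under this convention (a trapezoidal rule would
give 0.5).

Unlike the plain ROC curve, the surface metrics depend on the class
ratio, so the true positive and true negative labels are not
exchangeable: relabeling (with score negation) preserves AUC but
generally changes VUS and FCAUC.
"""

from __future__ import annotations

import numpy as np

from .curves import RocsCurve, ValidationError

__all__ = ["auc", "vus", "fcauc"]


def _tpr_steps(tpr: np.ndarray) -> np.ndarray:
    return np.diff(tpr, prepend=0.0)


def auc(curve: RocsCurve) -> float:
    """Area under the ROC curve by step summation over TPR levels."""
    return float(np.sum(_tpr_steps(curve.tpr) * (1.0 - curve.fpr)))


def vus(curve: RocsCurve) -> float:
    """Volume under the ROC surface: the TDR-weighted AUC.

    Equals :func:`auc` when TDR is identically one, and more generally
    down-weights TPR gains made at low precision.
    """
    return float(np.sum(_tpr_steps(curve.tpr) * curve.tdr * (1.0 - curve.fpr)))


def fcauc(curve: RocsCurve, b: float) -> float:
    """FDR-controlled AUC at acceptable false-discovery level ``b``.

    Scans all cutoffs for realized FDR at or below ``b`` (the empirical
    FDR need not be monotone, so every cutoff is checked) and takes the
    most liberal — the one with the largest discovery set. The ROC curve
    is capped at that cutoff's TPR and the capped area returned. If no
    cutoff attains ``FDR <= b`` the value is 0; at ``b = 1`` it equals
    the full AUC.
    """
    b = float(b)
    if not 0.0 <= b <= 1.0:
        raise ValidationError(f"FDR threshold must lie in [0, 1], got {b}")
    admissible = np.flatnonzero(curve.fdr <= b)
    if admissible.size == 0:
        return 0.0
    t_star = curve.tpr[admissible[-1]]
    capped = np.minimum(curve.tpr, t_star)
    return float(np.sum(_tpr_steps(capped) * (1.0 - curve.fpr)))
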