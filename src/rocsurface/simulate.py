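"""Two-class Gaussian simulations for exercising the surface metrics.

The generator draws both classes from normal distributions with a shared
standard deviation (one by default), the design used throughout the
demonstration experiments: the negative-class mean fixed at zero and the
positive-class mean set by the desired separation. Two experiment
drivers are provided:

* :func:`vus_fcauc_grid` — mean VUS and FCAUC over a (separation x
  class-ratio) grid, each cell averaged over independent replicate
  datasets.
* :func:`size_power_experiment` — the empirical rejection rate of the
  two-surface bootstrap test over replicated study pairs, used both to
  check the size of the test (equal positive-class means) and its power
  (unequal means).

Class counts are derived from a total sample size and a negative:positive
ratio ``r``: ``n_pos = round(n_total / (1 + r))`` (at least 1) and
``n_neg = n_total - n_pos``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import LabeledScores, ValidationError, compute_curve, orient
from .inference import TwoStudies, two_rocs_test
from . import metrics

__all__ = [
    "SimConfig",
    "gaussian_two_class",
    "split_counts",
    "vus_fcauc_grid",
    "size_power_experiment",
]

GRID_COLUMNS = ["distance", "ratio", "mean_vus", "mean_fcauc", "n_reps"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one two-class Gaussian dataset."""

    mu_pos: float
    mu_neg: float = 0.0
    sigma: float = 1.0
    n_neg: int = 1000
    n_pos: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.n_neg < 1 or self.n_pos < 1:
            raise ValidationError("class counts must be at least 1")


def gaussian_two_class(config: SimConfig) -> LabeledScores:
    """Draw one labeled dataset: ``n_neg`` scores from N(mu_neg, sigma)
    and ``n_pos`` from N(mu_pos, sigma). Negatives precede positives in
    the output; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    neg = rng.normal(config.mu_neg, config.sigma, config.n_neg)
    pos = rng.normal(config.mu_pos, config.sigma, config.n_pos)
    labels = np.r_[np.zeros(config.n_neg, bool), np.ones(config.n_pos, bool)]
    return LabeledScores(np.concatenate([neg, pos]), labels)


def split_counts(n_total: int, ratio: float) -> tuple[int, int]:
    """Split a total sample size into (n_pos, n_neg) at negative:positive
    ratio ``ratio``, rounding the positive count to nearest (minimum 1)."""
    if n_total < 2:
        raise ValidationError("n_total must be at least 2")
    if ratio < 1:
        raise ValidationError("class ratio must be >= 1 (negatives dominate)")
    n_pos = max(1, int(np.floor(n_total / (1 + ratio) + 0.5)))
    return n_pos, n_total - n_pos


def vus_fcauc_grid(
    distances,
    ratios,
    n_total: int = 2000,
    reps: int = 50,
    b: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean VUS and FCAUC over a separation-by-class-ratio grid.

    For every (distance, ratio) cell, ``reps`` independent datasets of
    ``n_total`` samples are generated (positives N(distance, 1),
    negatives N(0, 1)) and the mean VUS and mean FCAUC (at FDR level
    ``b``) recorded. Returns a long-format DataFrame with columns
    ``distance, ratio, mean_vus, mean_fcauc, n_reps``.
    """
    distances = list(distances)
    ratios = list(ratios)
    if not distances or not ratios:
        raise ValidationError("distance and ratio sweeps must be non-empty")
    if reps < 1:
        raise ValidationError("reps must be at least 1")
    seeds = np.random.SeedSequence(seed).spawn(len(distances) * len(ratios))
    rows = []
    cell = 0
    for distance in distances:
        for ratio in ratios:
            n_pos, n_neg = split_counts(n_total, ratio)
            rng = np.random.default_rng(seeds[cell])
            cell += 1
            vus_vals = np.empty(reps)
            fcauc_vals = np.empty(reps)
            for rep in range(reps):
                config = SimConfig(
                    mu_pos=distance, n_neg=n_neg, n_pos=n_pos,
                    seed=rng.integers(2**31),
                )
                curve = compute_curve(orient(gaussian_two_class(config)))
                vus_vals[rep] = metrics.vus(curve)
                fcauc_vals[rep] = metrics.fcauc(curve, b)
            rows.append(
                (distance, ratio, vus_vals.mean(), fcauc_vals.mean(), reps)
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def size_power_experiment(
    mu1: float,
    mu2: float,
    n1_total: int = 4000,
    n2_total: int = 4000,
    ratio1: float = 1.0,
    ratio2: float = 1.0,
    reps: int = 100,
    B: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the two-surface test over study pairs.

    Each replicate simulates study 1 (positives N(mu1, 1)) and study 2
    (positives N(mu2, 1)), negatives N(0, 1) in both, with the stated
    totals and negative:positive ratios, runs the bootstrap difference
    test with ``B`` resamples, and counts p-values below ``alpha``.
    With ``mu1 == mu2`` the null holds and the rate estimates the size of
    the test; otherwise it estimates power.
    """
    if reps < 1 or B < 1:
        raise ValidationError("reps and B must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie strictly between 0 and 1")
    n1_pos, n1_neg = split_counts(n1_total, ratio1)
    n2_pos, n2_neg = split_counts(n2_total, ratio2)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        study1 = gaussian_two_class(
            SimConfig(mu_pos=mu1, n_neg=n1_neg, n_pos=n1_pos,
                      seed=rng.integers(2**31))
        )
        study2 = gaussian_two_class(
            SimConfig(mu_pos=mu2, n_neg=n2_neg, n_pos=n2_pos,
                      seed=rng.integers(2**31))
        )
        result = two_rocs_test(
            TwoStudies(study1, study2), B=B, seed=int(rng.integers(2**31))
        )
        if result.p_value < alpha:
            rejections += 1
    return rejections / reps
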