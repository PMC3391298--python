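"""Delimited-text readers and writers for scores, curves and grids.

Two kinds of input are accepted: raw per-feature score tables with a
binary truth-label column, and precomputed operating-point tables giving
FPR, TPR and FDR directly (for results produced by external tools). The
delimiter (comma or tab) is sniffed; a header row is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import LabeledScores, RocsCurve, ValidationError

__all__ = [
    "ScoreTableSpec",
    "CurveTableSpec",
    "read_scores",
    "read_curve",
    "write_curve",
]


class MissingColumnError(ValidationError):
    """A named column is absent from the table."""


class UnparseableScoreError(ValidationError):
    """A score cell could not be parsed as a real number."""


class SingleClassError(ValidationError):
    """All labels map to one class."""


@dataclass(frozen=True)
class ScoreTableSpec:
    """Where and how to read a raw score table."""

    path: str | Path
    score_column: str = "score"
    label_column: str = "label"
    positive_value: str = "1"


@dataclass(frozen=True)
class CurveTableSpec:
    """Where and how to read a precomputed operating-point table."""

    path: str | Path
    fpr_column: str = "fpr"
    tpr_column: str = "tpr"
    fdr_column: str = "fdr"


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_scores(spec: ScoreTableSpec) -> LabeledScores:
    """Read per-feature scores and binary labels from a delimited table.

    Label cells equal (as strings) to ``spec.positive_value`` become the
    true positive class; everything else is negative. Row order is
    preserved.
    """
    table = _read_table(spec.path)
    for column in (spec.score_column, spec.label_column):
        if column not in table.columns:
            raise MissingColumnError(
                f"column {column!r} not found in {spec.path} "
                f"(have {list(table.columns)})"
            )
    scores = pd.to_numeric(table[spec.score_column], errors="coerce")
    if scores.isna().any():
        bad = table.index[scores.isna()].tolist()
        raise UnparseableScoreError(
            f"unparseable score values at rows {bad} of {spec.path}"
        )
    labels = (
        table[spec.label_column].astype(str).str.strip()
        == str(spec.positive_value)
    )
    if labels.all() or not labels.any():
        raise SingleClassError(
            f"single-class input: every label in {spec.path} maps to "
            f"{'positive' if labels.all() else 'negative'}"
        )
    return LabeledScores(scores.to_numpy(float), labels.to_numpy(bool))


def read_curve(spec: CurveTableSpec) -> RocsCurve:
    """Read a user-supplied FPR/TPR/FDR table as an operating-point curve.

    Rows are re-ordered to non-decreasing TPR (stable, so input order is
    preserved among ties), TDR is derived as 1 - FDR, and thresholds are
    synthesized as the descending row index since the original cutoffs
    are unknown. Class counts are likewise unknown and left unset.
    """
    table = _read_table(spec.path)
    for column in (spec.fpr_column, spec.tpr_column, spec.fdr_column):
        if column not in table.columns:
            raise MissingColumnError(
                f"column {column!r} not found in {spec.path} "
                f"(have {list(table.columns)})"
            )
    rates = table[[spec.fpr_column, spec.tpr_column, spec.fdr_column]].apply(
        pd.to_numeric, errors="coerce"
    )
    out_of_range = rates.isna() | (rates < 0) | (rates > 1)
    if out_of_range.any().any():
        bad = table.index[out_of_range.any(axis=1)].tolist()
        raise ValidationError(
            f"FPR/TPR/FDR values outside [0, 1] at rows {bad} of {spec.path}"
        )
    rates = rates.sort_values(spec.tpr_column, kind="stable")
    n = len(rates)
    return RocsCurve(
        thresholds=np.arange(n, 0, -1, dtype=float),
        fpr=rates[spec.fpr_column].to_numpy(float),
        tpr=rates[spec.tpr_column].to_numpy(float),
        fdr=rates[spec.fdr_column].to_numpy(float),
    )


def write_curve(curve: RocsCurve, path: str | Path) -> None:
    """Write a curve as CSV with threshold, fpr, tpr, fdr, tdr columns."""
    pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "fpr": curve.fpr,
            "tpr": curve.tpr,
            "fdr": curve.fdr,
            "tdr": curve.tdr,
        }
    ).to_csv(path, index=False)
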