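"""Fuzzy comprehensive evaluation of sensory panel data.

A trained panel grades each attribute (appearance, aroma, taste,
typicality) into ordinal categories (excellent, good, general, worse).
The grade counts for an attribute, divided by panel size, form a fuzzy
membership row; stacking the rows gives the relationship matrix R.
With attribute weights X (summing to 1) and grade scores P (points per
grade), the comprehensive score is the bilinear form

    Y = X . R . P^T

which is a weight-averaged, grade-score-weighted expectation: it always
lies between min(P) and max(P).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensoryPanel",
    "FuzzyResult",
    "DEFAULT_WEIGHTS",
    "DEFAULT_GRADE_SCORES",
    "counts_to_rating_matrix",
    "fuzzy_score",
    "panel_from_csv",
    "panel_to_csv",
]

DEFAULT_ATTRIBUTES = ("appearance", "aroma", "taste", "typicality")
DEFAULT_GRADES = ("excellent", "good", "general", "worse")
#: subjective attribute weights: appearance, aroma, taste, typicality
DEFAULT_WEIGHTS = (0.2, 0.25, 0.3, 0.25)
#: points awarded per grade, best to worst
DEFAULT_GRADE_SCORES = (100.0, 75.0, 50.0, 25.0)


@dataclass(frozen=True)
class SensoryPanel:
    """Grade-count table for one sample plus weights and grade scores."""

    attributes: tuple[str, ...]
    grades: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]  # attributes x grades
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    grade_scores: tuple[float, ...] = DEFAULT_GRADE_SCORES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.attributes), len(self.grades)):
            raise ValueError(
                f"counts shape {c.shape} does not match "
                f"{len(self.attributes)} attributes x {len(self.grades)} grades"
            )
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        row_sums = set(c.sum(axis=1).tolist())
        if len(row_sums) != 1:
            raise ValueError(
                f"every attribute must be rated by the same panel; row sums {sorted(row_sums)}"
            )
        if row_sums.pop() == 0:
            raise ValueError("panel size is zero")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {sum(self.weights)}, not 1")
        if len(self.weights) != len(self.attributes):
            raise ValueError("one weight per attribute required")
        if len(self.grade_scores) != len(self.grades):
            raise ValueError("one score per grade required")

    @property
    def n_panelists(self) -> int:
        return int(np.asarray(self.counts)[0].sum())


@dataclass(frozen=True)
class FuzzyResult:
    """Rating matrix, per-attribute scores and the comprehensive score Y."""

    rating_matrix: tuple[tuple[float, ...], ...]
    attribute_scores: tuple[float, ...]
    score: float


def counts_to_rating_matrix(panel: SensoryPanel) -> np.ndarray:
    """Normalize grade counts to per-attribute proportions (rows sum to 1)."""
    c = np.asarray(panel.counts, dtype=float)
    return c / c.sum(axis=1, keepdims=True)


def fuzzy_score(
    R: np.ndarray | Sequence[Sequence[float]],
    X: Sequence[float] = DEFAULT_WEIGHTS,
    P: Sequence[float] = DEFAULT_GRADE_SCORES,
) -> FuzzyResult:
    """Compute Y = X . R . P^T for an attribute-major rating matrix.

    ``R`` has one row per attribute and one column per grade; each row
    must sum to 1 (within 1e-9).  ``attribute_scores`` is the
    intermediate R . P^T, i.e. the expected grade score per attribute.
    """
    R = np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float)
    if R.ndim != 2 or R.shape != (len(X), len(P)):
        raise ValueError(
            f"rating matrix shape {R.shape} does not match {len(X)} weights x {len(P)} grades"
        )
    bad = np.abs(R.sum(axis=1) - 1.0) > 1e-9
    if bad.any():
        rows = np.nonzero(bad)[0].tolist()
        raise ValueError(f"rating-matrix rows {rows} do not sum to 1")
    attr = R @ P
    y = float(X @ attr)
    return FuzzyResult(
        rating_matrix=tuple(tuple(row) for row in R),
        attribute_scores=tuple(float(a) for a in attr),
        score=y,
    )


def score_panel(panel: SensoryPanel) -> FuzzyResult:
    """Convenience: counts -> rating matrix -> comprehensive score."""
    return fuzzy_score(
        counts_to_rating_matrix(panel), panel.weights, panel.grade_scores
    )


def panel_to_csv(panel: SensoryPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        np.asarray(panel.counts),
        index=list(panel.attributes),
        columns=list(panel.grades),
    )
    df.index.name = "attribute"
    df.to_csv(path, encoding="utf-8")


def panel_from_csv(
    path: str | Path,
    weights: Sequence[float] | None = None,
    grade_scores: Sequence[float] | None = None,
) -> SensoryPanel:
    """Rows = attributes, columns = grade counts; first column names attributes."""
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    return SensoryPanel(
        attributes=tuple(str(a) for a in df.index),
        grades=tuple(str(g) for g in df.columns),
        counts=tuple(tuple(int(v) for v in row) for row in df.to_numpy()),
        weights=tuple(weights) if weights is not None else DEFAULT_WEIGHTS,
        grade_scores=(
            tuple(grade_scores) if grade_scores is not None else DEFAULT_GRADE_SCORES
        ),
    )
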