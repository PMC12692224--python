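"""Simplex-lattice mixture designs over strain-inoculation proportions.

A mixture experiment varies the *proportions* of q components (here,
co-cultured lactic acid bacteria strains) under the constraint that the
proportions are non-negative and sum to one, i.e. the design region is
the (q-1)-simplex.  The {q, m} simplex-lattice design places runs at
every composition whose entries are multiples of 1/m; it contains
C(q+m-1, m) points and supports Scheffe polynomials up to degree m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Composition",
    "MixtureDesign",
    "ValidationError",
    "validate_composition",
    "generate_simplex_lattice",
    "augment_design",
    "design_to_csv",
    "design_from_csv",
]

#: entries of a stored composition sum to 1 within this tolerance
SUM_TOL_INTERNAL = 1e-9
#: raw input vectors may deviate from sum 1 by this much before rejection
SUM_TOL_INPUT = 1e-6


class ValidationError(ValueError):
    """Raised when a vector is not a valid point on the simplex."""


@dataclass(frozen=True)
class Composition:
    """A point on the (q-1)-simplex: non-negative proportions summing to 1."""

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValidationError("a composition needs at least two components")
        if np.any(p < 0) or np.any(p > 1):
            bad = int(np.argmax((p < 0) | (p > 1)))
            raise ValidationError(
                f"proportion {bad} = {p[bad]!r} outside [0, 1]"
            )
        if abs(p.sum() - 1.0) > SUM_TOL_INTERNAL:
            raise ValidationError(
                f"proportions sum to {p.sum()!r}, not 1 (tol {SUM_TOL_INTERNAL})"
            )

    @property
    def q(self) -> int:
        return len(self.proportions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)

    def __iter__(self):
        return iter(self.proportions)


def validate_composition(x: Sequence[float] | np.ndarray) -> Composition:
    """Validate and exactly renormalize a raw proportion vector.

    Accepts vectors whose entries lie in [0, 1] and whose sum is within
    1e-6 of one (CSV round-trips of thirds land here); the result is
    renormalized so that the stored sum is exactly 1 in floating point.

    Raises
    ------
    ValidationError
        If an entry is negative, exceeds 1, or the sum deviates from 1
        by more than the input tolerance.  The message names the
        offending entry or reports the sum.
    """
    p = np.asarray(x, dtype=float)
    if p.ndim != 1:
        raise ValidationError("composition must be a 1-D vector")
    for i, v in enumerate(p):
        if not np.isfinite(v):
            raise ValidationError(f"proportion {i} = {v!r} is not finite")
        if v < 0:
            raise ValidationError(f"proportion {i} = {v!r} is negative")
        if v > 1 + SUM_TOL_INPUT:
            raise ValidationError(f"proportion {i} = {v!r} exceeds 1")
    total = float(p.sum())
    if abs(total - 1.0) > SUM_TOL_INPUT:
        raise ValidationError(
            f"proportions sum to {total!r}; |sum - 1| exceeds {SUM_TOL_INPUT}"
        )
    p = np.clip(p / total, 0.0, 1.0)
    # force an exact floating-point sum of 1 by absorbing the residual
    # into the largest entry
    residual = 1.0 - p.sum()
    p[int(np.argmax(p))] += residual
    return Composition(tuple(float(v) for v in p))


@dataclass(frozen=True)
class MixtureDesign:
    """An ordered list of design points with component labels.

    ``replicates`` is the number of independent runs per point when the
    design is realized at the bench (or simulated).
    """

    q: int
    m: int
    points: tuple[Composition, ...]
    labels: tuple[str, ...] = field(default=())
    replicates: int = 1

    def __post_init__(self) -> None:
        labels = self.labels or tuple(f"X{i+1}" for i in range(self.q))
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) != self.q:
            raise ValueError(f"expected {self.q} labels, got {len(self.labels)}")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")
        for pt in self.points:
            if pt.q != self.q:
                raise ValueError("design point dimension mismatch")
        seen = {tuple(np.round(pt.as_array(), 12)) for pt in self.points}
        if len(seen) != len(self.points):
            raise ValueError("design points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    def as_matrix(self) -> np.ndarray:
        return np.array([pt.as_array() for pt in self.points])


def _lattice_points(q: int, m: int) -> Iterable[tuple[int, ...]]:
    """Integer compositions of m into q parts, lexicographically descending."""
    if q == 1:
        yield (m,)
        return
    for first in range(m, -1, -1):
        for rest in _lattice_points(q - 1, m - first):
            yield (first, *rest)


def generate_simplex_lattice(
    q: int, m: int, labels: Sequence[str] | None = None, replicates: int = 1
) -> MixtureDesign:
    """Generate the {q, m} simplex-lattice design.

    Returns all C(q+m-1, m) compositions whose proportions are multiples
    of 1/m, ordered lexicographically descending so that repeated calls
    (and exported files) are byte-identical.
    """
    if not isinstance(q, (int, np.integer)) or q < 2:
        raise ValueError(f"q must be an integer >= 2, got {q!r}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be an integer >= 1, got {m!r}")
    points = tuple(
        validate_composition(np.array(c, dtype=float) / m)
        for c in _lattice_points(int(q), int(m))
    )
    assert len(points) == comb(q + m - 1, m)
    design = MixtureDesign(
        q=int(q),
        m=int(m),
        points=points,
        labels=tuple(labels) if labels else (),
        replicates=replicates,
    )
    return design


def _contains(points: Sequence[Composition], candidate: Composition) -> bool:
    c = candidate.as_array()
    return any(np.allclose(pt.as_array(), c, atol=1e-12) for pt in points)


def augment_design(
    design: MixtureDesign, centroid: bool = False, axial: bool = False
) -> MixtureDesign:
    """Append the overall centroid and/or axial points to a design.

    The centroid is (1/q, ..., 1/q).  Axial points sit halfway between
    the centroid and each vertex: (q+1)/(2q) on one axis and 1/(2q)
    elsewhere.  Points already present are not duplicated, so augmenting
    twice is a no-op.
    """
    q = design.q
    extra: list[Composition] = []
    if centroid:
        extra.append(validate_composition(np.full(q, 1.0 / q)))
    if axial:
        for i in range(q):
            x = np.full(q, 1.0 / (2 * q))
            x[i] = (q + 1) / (2 * q)
            extra.append(validate_composition(x))
    points = list(design.points)
    for cand in extra:
        if not _contains(points, cand):
            points.append(cand)
    return replace(design, points=tuple(points))


def design_to_csv(design: MixtureDesign, path: str | Path) -> None:
    """Write one row per design point; columns are the component labels."""
    df = pd.DataFrame(design.as_matrix(), columns=list(design.labels))
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def design_from_csv(path: str | Path, m: int | None = None) -> MixtureDesign:
    """Read a design written by :func:`design_to_csv`.

    Each row is validated; a sum-violating row raises ValidationError
    naming the row.  ``m`` is recorded on the returned design when known
    (it is not recoverable from an arbitrary point list).
    """
    df = pd.read_csv(path, encoding="utf-8")
    labels = tuple(str(c) for c in df.columns)
    points = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            points.append(validate_composition(np.asarray(row, dtype=float)))
        except ValidationError as err:
            raise ValidationError(f"row {i + 1}: {err}") from err
    return MixtureDesign(
        q=len(labels), m=m if m is not None else 0, points=tuple(points), labels=labels
    )
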