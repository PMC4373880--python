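"""Balanced and unbalanced 2x2 cell-count designs.

The study universe is every way of splitting 12 subjects over the four
cells of a two-by-two factorial with at least two subjects per cell (so
every cell retains within-cell variance).  There are 35 such
compositions: one balanced, (3, 3, 3, 3), and 34 unbalanced ones.  Each
is scaled by 10 for the simulation study, giving N = 120 with cell
sizes in {20, 30, 40, 50, 60}.

Cells are indexed (a, b) with level 0 = control and 1 = treatment, in
the fixed order (0,0), (0,1), (1,0), (1,1).  Unbalanced designs are
numbered 1..34 in lexicographic order of (n00, n01, n10, n11).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

__all__ = [
    "DesignCounts",
    "ImbalanceIndicator",
    "enumerate_compositions",
    "study_designs",
    "balanced_design",
    "imbalance",
    "BASE_TOTAL",
    "BASE_MIN_PER_CELL",
    "STUDY_SCALE",
]

#: base (unscaled) total count and per-cell minimum of the study universe
BASE_TOTAL = 12
BASE_MIN_PER_CELL = 2
#: every base cell count is multiplied by this for the simulation study
STUDY_SCALE = 10

CELL_LABELS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class DesignCounts:
    """Subject counts per cell of a 2x2 design, cell order (0,0), (0,1), (1,0), (1,1)."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"cell count {name}={value!r} must be a non-negative integer")
            object.__setattr__(self, name, int(value))
        if self.total == 0:
            raise ValueError("design has no subjects")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n00, self.n01, self.n10, self.n11)

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def is_balanced(self) -> bool:
        return len(set(self.counts)) == 1

    def scaled(self, factor: int) -> "DesignCounts":
        """Multiply every cell count by ``factor``."""
        if int(factor) != factor or factor < 1:
            raise ValueError(f"scale factor must be a positive integer, got {factor!r}")
        return DesignCounts(*(factor * c for c in self.counts))

    def swap_factors(self) -> "DesignCounts":
        """Relabel A as B and vice versa (transpose the 2x2 count table)."""
        return DesignCounts(self.n00, self.n10, self.n01, self.n11)

    def min_count(self) -> int:
        return min(self.counts)


@dataclass(frozen=True)
class ImbalanceIndicator:
    """Signed imbalance fraction per effect, each in [-1, 1].

    For an effect V the indicator is (f_{V=T} - f_{V=C}) / N: the count
    of subjects on the treatment side of V minus the count on the
    control side, as a fraction of the total.  For the interaction the
    "treatment" side is the concordant diagonal, cells (0,0) and (1,1),
    matching the sum-to-zero view in which the product code is +1 there.
    All three are zero for a balanced design.
    """

    u_a: float
    u_b: float
    u_ab: float

    @property
    def as_tuple(self) -> tuple[float, float, float]:
        return (self.u_a, self.u_b, self.u_ab)


def enumerate_compositions(n: int, k: int, min_per_cell: int = 0) -> list[tuple[int, ...]]:
    """Every ordered composition of ``n`` into ``k`` parts, each >= ``min_per_cell``.

    Returned in lexicographic order, without duplicates.  The number of
    compositions is C(n - k*min_per_cell + k - 1, k - 1); an infeasible
    bound (n < k*min_per_cell) yields an empty list.
    """
    if int(n) != n or int(k) != k or n <= 0 or k <= 0:
        raise ValueError(f"n and k must be positive integers, got n={n!r}, k={k!r}")
    if int(min_per_cell) != min_per_cell or min_per_cell < 0:
        raise ValueError(f"min_per_cell must be a non-negative integer, got {min_per_cell!r}")
    out: list[tuple[int, ...]] = []

    def _extend(prefix: tuple[int, ...], remaining: int, cells_left: int) -> None:
        if cells_left == 1:
            if remaining >= min_per_cell:
                out.append(prefix + (remaining,))
            return
        upper = remaining - min_per_cell * (cells_left - 1)
        for first in range(min_per_cell, upper + 1):
            _extend(prefix + (first,), remaining - first, cells_left - 1)

    _extend((), int(n), int(k))
    assert len(out) == len(set(out))
    return out


def composition_count(n: int, k: int, min_per_cell: int = 0) -> int:
    """Closed-form count of the compositions ``enumerate_compositions`` returns."""
    free = n - k * min_per_cell
    if free < 0:
        return 0
    return comb(free + k - 1, k - 1)


def balanced_design(scale: int = STUDY_SCALE) -> DesignCounts:
    """The balanced counterpart (3, 3, 3, 3) x scale of the study designs."""
    return DesignCounts(3, 3, 3, 3).scaled(scale)


def study_designs(scale: int = STUDY_SCALE) -> list[DesignCounts]:
    """The 34 unbalanced designs of the study, numbered 1..34 by list position + 1.

    These are the compositions of 12 into 4 cells with at least 2 per
    cell, excluding the balanced (3, 3, 3, 3), in lexicographic order of
    (n00, n01, n10, n11), each scaled by ``scale`` (the study uses 10,
    for N = 120).
    """
    designs = [
        DesignCounts(*c).scaled(scale)
        for c in enumerate_compositions(BASE_TOTAL, 4, BASE_MIN_PER_CELL)
        if len(set(c)) > 1
    ]
    assert len(designs) == 34
    return designs


def imbalance(design: DesignCounts) -> ImbalanceIndicator:
    """Per-effect imbalance indicator of a design (see :class:`ImbalanceIndicator`)."""
    n00, n01, n10, n11 = design.counts
    total = design.total
    return ImbalanceIndicator(
        u_a=(n10 + n11 - n00 - n01) / total,
        u_b=(n01 + n11 - n00 - n10) / total,
        u_ab=(n00 + n11 - n01 - n10) / total,
    )
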