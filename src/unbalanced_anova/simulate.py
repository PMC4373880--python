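"""Synthetic 2x2 outcome data under a linear model with two effect constructions.

Outcomes follow ``y = beta0 + beta1*cA + beta2*cB + beta3*cA*cB + eps``
with i.i.d. normal noise eps ~ N(0, sigma^2).  The numeric codes
``(cA, cB)`` substituted for the factor levels are fixed by the effect
*construction*, not by the analysis:

``zero_control``
    codes (0, 1): control groups contribute nothing, only treatment
    cells carry the effects (a no-treatment-control scenario).

``equal_contribution``
    codes (-1, 1): control and treatment groups contribute equally and
    oppositely; the interaction contrasts the concordant diagonal with
    the discordant one.

Factor levels are stored abstractly as 0/1; the analysis chooses its
own coding later, which is what makes congruous versus incongruous
analysis possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .designs import CELL_LABELS, DesignCounts

__all__ = [
    "CONSTRUCTIONS",
    "EffectSpec",
    "SampleData",
    "cell_means",
    "generate_sample",
    "generate_paired",
]

CONSTRUCTIONS = ("zero_control", "equal_contribution")

_CODES = {"zero_control": (0.0, 1.0), "equal_contribution": (-1.0, 1.0)}

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


@dataclass(frozen=True)
class EffectSpec:
    """Generating parameters of the linear model (study defaults).

    beta0 is the intercept, beta1/beta2 the main-effect coefficients,
    beta3 the interaction coefficient, all in outcome units; sigma is
    the residual standard deviation.  The study keeps beta0=10,
    beta1=beta2=4, sigma=10 and varies beta3 over {0, 4, 8}.
    """

    beta0: float = 10.0
    beta1: float = 4.0
    beta2: float = 4.0
    beta3: float = 0.0
    sigma: float = 10.0
    construction: str = "zero_control"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        if self.construction not in CONSTRUCTIONS:
            raise ValueError(
                f"construction must be one of {CONSTRUCTIONS}, got {self.construction!r}"
            )

    @property
    def codes(self) -> tuple[float, float]:
        """(control, treatment) numeric codes of this construction."""
        return _CODES[self.construction]

    def cell_means(self) -> np.ndarray:
        """Noise-free expected outcome per cell, order (0,0), (0,1), (1,0), (1,1)."""
        lo, hi = self.codes
        code = (lo, hi)
        return np.array(
            [
                self.beta0
                + self.beta1 * code[a]
                + self.beta2 * code[b]
                + self.beta3 * code[a] * code[b]
                for a, b in CELL_LABELS
            ]
        )


@dataclass(frozen=True, eq=False)
class SampleData:
    """Per-subject records of a simulated (or imported) 2x2 dataset.

    ``a`` and ``b`` hold factor level indices (0 = control,
    1 = treatment); ``y`` the outcome.  ``design`` records the cell
    counts, which must match the data.
    """

    a: np.ndarray
    b: np.ndarray
    y: np.ndarray
    design: DesignCounts
    spec: EffectSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.int64)
        b = np.asarray(self.b, dtype=np.int64)
        y = np.asarray(self.y, dtype=float)
        if not (a.shape == b.shape == y.shape) or a.ndim != 1:
            raise ValueError("a, b and y must be one-dimensional arrays of equal length")
        if not np.isin(a, (0, 1)).all() or not np.isin(b, (0, 1)).all():
            raise ValueError("factor levels must be 0 (control) or 1 (treatment)")
        if not np.isfinite(y).all():
            raise ValueError("outcome contains non-finite values")
        counts = np.bincount(a * 2 + b, minlength=4)
        if tuple(counts) != self.design.counts:
            raise ValueError(
                f"cell counts {tuple(counts)} do not match design {self.design.counts}"
            )
        for name, arr in (("a", a), ("b", b), ("y", y)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.y.size

    @property
    def cell_index(self) -> np.ndarray:
        """Flat cell index 2*a + b per subject (0..3 in the canonical cell order)."""
        return self.a * 2 + self.b

    def to_frame(self) -> pd.DataFrame:
        """Subjects as a DataFrame with columns a, b ('C'/'T') and y."""
        levels = np.array(["C", "T"])
        return pd.DataFrame({"a": levels[self.a], "b": levels[self.b], "y": self.y})

    @classmethod
    def from_arrays(
        cls, a: np.ndarray, b: np.ndarray, y: np.ndarray, spec: EffectSpec | None = None
    ) -> "SampleData":
        """Build a sample, inferring the design from the observed cell counts."""
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        counts = np.bincount(a * 2 + b, minlength=4)
        return cls(a=a, b=b, y=np.asarray(y, float), design=DesignCounts(*counts), spec=spec)

    def equals(self, other: "SampleData") -> bool:
        return (
            self.design == other.design
            and np.array_equal(self.a, other.a)
            and np.array_equal(self.b, other.b)
            and np.array_equal(self.y, other.y)
        )


def cell_means(spec: EffectSpec) -> np.ndarray:
    """Noise-free expected cell means of ``spec`` (order (0,0), (0,1), (1,0), (1,1))."""
    return spec.cell_means()


def _as_generator(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _level_arrays(design: DesignCounts) -> tuple[np.ndarray, np.ndarray]:
    a = np.repeat([lab[0] for lab in CELL_LABELS], design.counts)
    b = np.repeat([lab[1] for lab in CELL_LABELS], design.counts)
    return a, b


def generate_sample(design: DesignCounts, spec: EffectSpec, seed: SeedLike = None) -> SampleData:
    """Draw one sample: per cell, count-many outcomes = cell mean + N(0, sigma) noise.

    Subjects are ordered by cell, (0,0) block first.  Reproducible given
    the same seed (an int, a SeedSequence or a Generator).
    """
    rng = _as_generator(seed)
    means = spec.cell_means()
    a, b = _level_arrays(design)
    y = np.concatenate(
        [
            means[i] + spec.sigma * rng.standard_normal(count)
            for i, count in enumerate(design.counts)
        ]
    )
    return SampleData(a=a, b=b, y=y, design=design, spec=spec)


def generate_paired(
    design: DesignCounts,
    balanced: DesignCounts,
    spec: EffectSpec,
    seed: SeedLike = None,
) -> tuple[SampleData, SampleData]:
    """Draw an unbalanced sample and its balanced counterpart from shared subjects.

    For each cell a pool of max(design count, balanced count) subjects is
    drawn once; the unbalanced sample takes the first design-count
    subjects of the pool and the balanced sample the first
    balanced-count, so the two samples share min(design, balanced)
    subjects per cell.  This common-random-numbers pairing reduces the
    Monte-Carlo variance of balanced-versus-unbalanced comparisons.
    """
    if design.total != balanced.total:
        raise ValueError(
            f"total counts differ: design N={design.total}, balanced N={balanced.total}"
        )
    rng = _as_generator(seed)
    means = spec.cell_means()
    y_unb, y_bal = [], []
    for i, (n_u, n_b) in enumerate(zip(design.counts, balanced.counts)):
        pool = means[i] + spec.sigma * rng.standard_normal(max(n_u, n_b))
        y_unb.append(pool[:n_u])
        y_bal.append(pool[:n_b])
    a_u, b_u = _level_arrays(design)
    a_b, b_b = _level_arrays(balanced)
    return (
        SampleData(a=a_u, b=b_u, y=np.concatenate(y_unb), design=design, spec=spec),
        SampleData(a=a_b, b=b_b, y=np.concatenate(y_bal), design=balanced, spec=spec),
    )
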