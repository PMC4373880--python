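"""Least-squares ANOVA engine for 2x2 factorials: nested fits, SS types, Venn components.

The engine owns the Type I/II/III definitions rather than delegating to
a statistics package.  Every sum of squares is a difference of
regression sums of squares R(S) over the seven non-empty predictor
subsets S of {A, B, AB}, where R(S) is the model SS (about the grand
mean) of an intercept-plus-S ordinary least-squares fit:

* Type I, A first:  SS(A) = R(A),        SS(B) = R(AB) - R(A)
* Type I, B first:  SS(B) = R(B),        SS(A) = R(AB) - R(B)
* Type II:          SS(A) = R(AB) - R(B), SS(B) = R(AB) - R(A)
* Type III:         SS(A) = R(ABI) - R(B,I), SS(B) = R(ABI) - R(A,I)
* interaction:      SS(AB) = R(ABI) - R(AB) for every type (the unique
  part z; Type II has no better-defined interaction row).

Commonality (Venn) components t..z are inclusion-exclusion combinations
of the same seven fits; the non-unique ones (u, v, w, y) may be
negative.  F tests use the full-model residual mean square on N - 4
degrees of freedom.

Because every predictor column is constant within a cell, each R(S) is
computed exactly from the per-cell sufficient statistics (counts and
means) by a weighted least-squares solve on the four cell rows; the
within-cell scatter enters only the total and residual SS.  This is
algebraically identical to the subject-level normal equations (the test
suite checks it against an explicit subject-level projection oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .designs import CELL_LABELS, DesignCounts
from .simulate import SampleData

__all__ = [
    "EFFECTS",
    "CODINGS",
    "RankDeficiencyError",
    "NestedFits",
    "VennComponents",
    "AnovaTable",
    "FactorialAnova",
    "design_matrix",
    "nested_fits",
    "ss_type1",
    "ss_type2",
    "ss_type3",
    "venn_components",
    "f_test",
]

EFFECTS = ("A", "B", "AB")
CODINGS = ("treatment", "contrast")

#: (control, treatment) numeric codes per analysis coding
_CODING_CODES = {"treatment": (0.0, 1.0), "contrast": (-1.0, 1.0)}

#: the seven non-empty predictor subsets, canonical order
SUBSETS = (
    frozenset({"A"}),
    frozenset({"B"}),
    frozenset({"AB"}),
    frozenset({"A", "B"}),
    frozenset({"A", "AB"}),
    frozenset({"B", "AB"}),
    frozenset({"A", "B", "AB"}),
)
_FULL = frozenset({"A", "B", "AB"})


class RankDeficiencyError(ValueError):
    """The design matrix of a requested fit is rank deficient (e.g. an empty cell)."""


def _cell_code_matrix(coding: str) -> np.ndarray:
    """4x4 matrix of [intercept, A, B, AB] codes for the cells in canonical order."""
    if coding not in _CODING_CODES:
        raise ValueError(f"coding must be one of {CODINGS}, got {coding!r}")
    lo, hi = _CODING_CODES[coding]
    code = (lo, hi)
    rows = [[1.0, code[a], code[b], code[a] * code[b]] for a, b in CELL_LABELS]
    return np.array(rows)


_COLUMN_OF = {"A": 1, "B": 2, "AB": 3}


@dataclass(frozen=True)
class NestedFits:
    """Regression SS of all seven predictor subsets plus the totals of one sample."""

    r: Mapping[frozenset, float]
    total_ss: float
    residual_ss: float
    df_resid: int
    n_obs: int
    coding: str

    def r_of(self, *terms: str) -> float:
        """R(S) for the subset given as term names, e.g. ``r_of('A', 'AB')``."""
        return self.r[frozenset(terms)]


@dataclass(frozen=True)
class VennComponents:
    """Commonality decomposition of the full-model SS.

    t, x, z are the unique SS of A, B and the interaction; w = common
    (A, AB), y = common(B, AB), u = common(A, B), v = common(A, B, AB).
    The non-unique components can be negative ("underlapping" variance).
    """

    t: float
    u: float
    v: float
    w: float
    x: float
    y: float
    z: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in "tuvwxyz"}


@dataclass(frozen=True)
class AnovaTable:
    """Per-effect SS with F tests against the full-model residual.

    Each effect has one degree of freedom; the residual has ``df_resid``
    = N - 4.  ``ss_type`` is one of 'I(A)', 'I(B)', 'II', 'III'.
    """

    ss: Mapping[str, float]
    residual_ss: float
    df_resid: int
    ss_type: str
    coding: str

    @property
    def ms_resid(self) -> float:
        return self.residual_ss / self.df_resid

    def f_stats(self) -> dict[str, float]:
        # a tiny negative SS from floating-point cancellation counts as zero signal;
        # a noise-free sample (zero residual) gives F = inf for any non-zero effect SS
        out = {}
        for e in EFFECTS:
            ss = max(self.ss[e], 0.0)
            if self.ms_resid > 0:
                out[e] = ss / self.ms_resid
            else:
                out[e] = np.inf if ss > 0 else 0.0
        return out

    def p_values(self) -> dict[str, float]:
        return {
            e: float(stats.f.sf(f, 1, self.df_resid)) for e, f in self.f_stats().items()
        }

    def to_frame(self) -> pd.DataFrame:
        f, p = self.f_stats(), self.p_values()
        rows = [
            {"effect": e, "ss": self.ss[e], "df": 1, "F": f[e], "p": p[e]}
            for e in EFFECTS
        ]
        rows.append(
            {
                "effect": "Residual",
                "ss": self.residual_ss,
                "df": self.df_resid,
                "F": np.nan,
                "p": np.nan,
            }
        )
        out = pd.DataFrame(rows)
        out.attrs["ss_type"] = self.ss_type
        out.attrs["coding"] = self.coding
        return out


def _normalize_ss_type(ss_type: str) -> str:
    key = str(ss_type).strip().upper().replace(" ", "")
    aliases = {
        "1": "I(A)", "I": "I(A)", "1A": "I(A)", "IA": "I(A)", "I(A)": "I(A)",
        "1B": "I(B)", "IB": "I(B)", "I(B)": "I(B)",
        "2": "II", "II": "II",
        "3": "III", "III": "III",
    }
    if key not in aliases:
        raise ValueError(f"unknown SS type {ss_type!r}")
    return aliases[key]


def _normalize_levels(values: np.ndarray, name: str) -> np.ndarray:
    """Map factor levels given as C/T, 0/1 or -1/1 onto level indices 0/1."""
    arr = np.asarray(values)
    if arr.dtype.kind in "OUS":
        up = np.char.upper(arr.astype(str))
        if not np.isin(up, ("C", "T")).all():
            raise ValueError(f"column {name!r}: string levels must be 'C'/'T'")
        return (up == "T").astype(np.int64)
    num = arr.astype(float)
    uniq = set(np.unique(num))
    if uniq <= {0.0, 1.0}:
        return num.astype(np.int64)
    if uniq <= {-1.0, 1.0}:
        return (num > 0).astype(np.int64)
    raise ValueError(f"column {name!r}: numeric levels must be 0/1 or -1/1, got {sorted(uniq)}")


def _coerce_input(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, SampleData):
        if y is not None:
            raise ValueError("y must be None when X is a SampleData")
        return X.a, X.b, X.y
    if isinstance(X, pd.DataFrame):
        cols = {c.lower(): c for c in X.columns}
        if not {"a", "b"} <= set(cols):
            raise ValueError("DataFrame input needs columns 'a' and 'b'")
        a = _normalize_levels(X[cols["a"]].to_numpy(), "a")
        b = _normalize_levels(X[cols["b"]].to_numpy(), "b")
        if y is None:
            if "y" not in cols:
                raise ValueError("DataFrame input needs a 'y' column (or pass y separately)")
            y = X[cols["y"]].to_numpy()
        return a, b, np.asarray(y, dtype=float)
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"X must be (n_samples, 2) factor levels, got shape {arr.shape}")
    if y is None:
        raise ValueError("y is required when X is an array of factor levels")
    return (
        _normalize_levels(arr[:, 0], "a"),
        _normalize_levels(arr[:, 1], "b"),
        np.asarray(y, dtype=float),
    )


def design_matrix(sample: SampleData | pd.DataFrame, coding: str = "contrast") -> np.ndarray:
    """Subject-level full design matrix [1, a, b, a*b] under ``coding``.

    Raises :class:`RankDeficiencyError` naming the first empty cell.
    """
    a, b, _y = _coerce_input(sample, None if isinstance(sample, (SampleData, pd.DataFrame)) else 0)
    counts = np.bincount(a * 2 + b, minlength=4)
    for (la, lb), count in zip(CELL_LABELS, counts):
        if count == 0:
            names = ("C", "T")
            raise RankDeficiencyError(
                f"cell ({names[la]}, {names[lb]}) is empty: the full 2x2 model is rank deficient"
            )
    codes = _cell_code_matrix(coding)
    return codes[a * 2 + b]


class FactorialAnova(BaseEstimator):
    """Two-by-two factorial ANOVA by explicit nested least squares.

    Parameters
    ----------
    coding : {'contrast', 'treatment'}
        Numeric codes for the factor levels in the analysis design
        matrix: sum-to-zero (-1, 1) or dummy (0, 1).  Type I/II SS and
        the unique interaction SS are invariant to this choice; Type III
        main-effect SS are not, and (-1, 1) is the recommended default.
    alpha : float
        Default significance level of :meth:`reject`.
    tol : float
        Relative singular-value cutoff of the least-squares solves.

    Attributes (after :meth:`fit`)
    ------------------------------
    nested_fits_ : NestedFits            R(S) for all seven subsets.
    venn_ : VennComponents               commonality decomposition t..z.
    coef_ : ndarray, shape (4,)          full-model [intercept, A, B, AB].
    cell_counts_ : DesignCounts          observed counts per cell.
    cell_means_ : ndarray, shape (4,)    observed means per cell.
    total_ss_, residual_ss_, df_resid_, n_obs_

    Examples
    --------
    >>> from unbalanced_anova import EffectSpec, FactorialAnova, balanced_design, generate_sample
    >>> sample = generate_sample(balanced_design(), EffectSpec(beta3=4.0), seed=1)
    >>> table = FactorialAnova(coding="contrast").fit(sample).anova_table("II")
    """

    def __init__(self, coding: str = "contrast", alpha: float = 0.05, tol: float = 1e-10):
        self.coding = coding
        self.alpha = alpha
        self.tol = tol

    def fit(self, X: Union[SampleData, pd.DataFrame, np.ndarray], y: np.ndarray | None = None):
        """Fit all seven nested models to a sample.

        ``X`` may be a :class:`~unbalanced_anova.simulate.SampleData`, a
        DataFrame with columns a, b, y, or an (n, 2) array of factor
        levels with ``y`` passed separately.  Levels may be coded C/T,
        0/1 or -1/1; the analysis coding is the estimator's own
        ``coding`` parameter regardless of the input encoding.
        """
        a, b, yv = _coerce_input(X, y)
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")
        counts = np.bincount(a * 2 + b, minlength=4)
        names = ("C", "T")
        for (la, lb), count in zip(CELL_LABELS, counts):
            if count == 0:
                raise RankDeficiencyError(
                    f"cell ({names[la]}, {names[lb]}) is empty: "
                    "the full 2x2 model is rank deficient"
                )
        n = yv.size
        if n - 4 < 1:
            raise ValueError(f"need at least 5 observations for a residual df, got {n}")

        cell = a * 2 + b
        sums = np.bincount(cell, weights=yv, minlength=4)
        means = sums / counts
        grand = yv.mean()
        between = float(counts @ (means - grand) ** 2)
        total = float(((yv - grand) ** 2).sum())

        codes = _cell_code_matrix(self.coding)
        sqrt_w = np.sqrt(counts.astype(float))
        r: dict[frozenset, float] = {}
        for subset in SUBSETS:
            cols = [0] + sorted(_COLUMN_OF[t] for t in subset)
            design = codes[:, cols]
            beta, _res, rank, _sv = np.linalg.lstsq(
                sqrt_w[:, None] * design, sqrt_w * means, rcond=self.tol
            )
            if rank < len(cols):
                raise RankDeficiencyError(
                    f"rank-deficient fit for predictor subset {sorted(subset)}"
                )
            fitted = design @ beta
            r[subset] = between - float(counts @ (means - fitted) ** 2)

        self.n_obs_ = n
        self.cell_counts_ = DesignCounts(*counts)
        self.cell_means_ = means
        self.total_ss_ = total
        self.residual_ss_ = total - r[_FULL]
        self.df_resid_ = n - 4
        self.coef_ = np.linalg.solve(codes, means)
        self.nested_fits_ = NestedFits(
            r=MappingProxyType(r),
            total_ss=total,
            residual_ss=self.residual_ss_,
            df_resid=self.df_resid_,
            n_obs=n,
            coding=self.coding,
        )
        self.venn_ = venn_components(self.nested_fits_)
        return self

    def anova_table(self, ss_type: str = "II") -> AnovaTable:
        """Per-effect SS, F and p for a sum-of-squares type ('1A', '1B', '2'/'II', '3'/'III')."""
        self._check_fitted()
        kind = _normalize_ss_type(ss_type)
        if kind == "I(A)":
            return ss_type1(self.nested_fits_, order="A")
        if kind == "I(B)":
            return ss_type1(self.nested_fits_, order="B")
        if kind == "II":
            return ss_type2(self.nested_fits_)
        return ss_type3(self.nested_fits_)

    def venn_components(self) -> VennComponents:
        self._check_fitted()
        return self.venn_

    def reject(self, ss_type: str = "II", alpha: float | None = None) -> dict[str, bool]:
        """Per-effect rejection flags of the F tests at ``alpha``."""
        return f_test(self.anova_table(ss_type), self.alpha if alpha is None else alpha)

    def _check_fitted(self) -> None:
        if not hasattr(self, "nested_fits_"):
            raise AttributeError("this FactorialAnova instance is not fitted yet")


def nested_fits(
    sample: SampleData | pd.DataFrame, coding: str = "contrast", tol: float = 1e-10
) -> NestedFits:
    """Regression SS of the seven nested models of a sample (see module docstring)."""
    return FactorialAnova(coding=coding, tol=tol).fit(sample).nested_fits_


def _table(fits: NestedFits, ss: dict[str, float], ss_type: str) -> AnovaTable:
    return AnovaTable(
        ss=MappingProxyType(ss),
        residual_ss=fits.residual_ss,
        df_resid=fits.df_resid,
        ss_type=ss_type,
        coding=fits.coding,
    )


def ss_type1(fits: NestedFits, order: str = "A") -> AnovaTable:
    """Sequential SS: first main effect unadjusted, second adjusted for the first."""
    if order not in ("A", "B"):
        raise ValueError(f"order must be 'A' or 'B', got {order!r}")
    first, second = ("A", "B") if order == "A" else ("B", "A")
    ss = {
        first: fits.r_of(first),
        second: fits.r_of("A", "B") - fits.r_of(first),
        "AB": fits.r_of("A", "B", "AB") - fits.r_of("A", "B"),
    }
    return _table(fits, {e: ss[e] for e in EFFECTS}, f"I({order})")


def ss_type2(fits: NestedFits) -> AnovaTable:
    """Each main effect adjusted for the other main effect; interaction gets its unique SS."""
    ss = {
        "A": fits.r_of("A", "B") - fits.r_of("B"),
        "B": fits.r_of("A", "B") - fits.r_of("A"),
        "AB": fits.r_of("A", "B", "AB") - fits.r_of("A", "B"),
    }
    return _table(fits, ss, "II")


def ss_type3(fits: NestedFits) -> AnovaTable:
    """Every effect adjusted for all others (unique SS; coding-dependent for main effects)."""
    ss = {
        "A": fits.r_of("A", "B", "AB") - fits.r_of("B", "AB"),
        "B": fits.r_of("A", "B", "AB") - fits.r_of("A", "AB"),
        "AB": fits.r_of("A", "B", "AB") - fits.r_of("A", "B"),
    }
    return _table(fits, ss, "III")


def venn_components(fits: NestedFits) -> VennComponents:
    """Inclusion-exclusion commonality decomposition over the seven nested fits."""
    r = fits.r_of
    return VennComponents(
        t=r("A", "B", "AB") - r("B", "AB"),
        x=r("A", "B", "AB") - r("A", "AB"),
        z=r("A", "B", "AB") - r("A", "B"),
        w=r("A", "B") + r("B", "AB") - r("B") - r("A", "B", "AB"),
        y=r("A", "B") + r("A", "AB") - r("A") - r("A", "B", "AB"),
        u=r("A", "AB") + r("B", "AB") - r("AB") - r("A", "B", "AB"),
        v=r("A", "B", "AB") + r("A") + r("B") + r("AB")
        - r("A", "B") - r("A", "AB") - r("B", "AB"),
    )


def f_test(table: AnovaTable, alpha: float = 0.05) -> dict[str, bool]:
    """Reject H0 per effect iff the upper-tail central-F probability is below alpha."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    return {e: p < alpha for e, p in table.p_values().items()}
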