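"""Monte-Carlo power study of balanced versus unbalanced 2x2 ANOVA.

For every (design, interaction strength, effect construction) cell the
study draws paired unbalanced/balanced samples sharing as many subjects
as possible, analyses the unbalanced sample with Type II and Type III
sums of squares (contrast coding) and the balanced counterpart with the
standard sequential analysis, and tallies per-effect rejections of H0
at alpha.  Rejection rates estimate the type-I error under H0 and the
power under H1.

A closed-form noncentral-F oracle (:func:`analytic_power`) provides an
independent check: the noncentrality of an effect is its noise-free SS
(the SS the engine assigns to the effect when every subject sits exactly
on its cell mean) divided by the error variance.

Comparisons against the balanced arm are made per design against that
design's *own* paired balanced arm, so the shared subjects cancel most
of the Monte-Carlo noise from the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import (
    EFFECTS,
    FactorialAnova,
    _normalize_ss_type,
    f_test,
    nested_fits,
    ss_type1,
    ss_type2,
    ss_type3,
)
from .designs import DesignCounts, study_designs
from .simulate import (
    CONSTRUCTIONS,
    EffectSpec,
    SampleData,
    _level_arrays,
    generate_paired,
    generate_sample,
)

__all__ = [
    "METHODS",
    "StudyGrid",
    "replicate_seed",
    "run_cell",
    "run_study",
    "analytic_power",
    "summarize_means",
    "compare_to_balanced",
    "coefficient_summary",
]

#: analysis arms of the study: sequential SS on the balanced counterpart,
#: Type II and Type III on the unbalanced sample (contrast coding throughout)
METHODS = ("balanced", "ss2", "ss3")

_REPORT_COLUMNS = [
    "design_id", "n00", "n01", "n10", "n11", "beta3", "construction",
    "method", "effect", "rate", "mc_se", "replicates",
]


@dataclass(frozen=True)
class StudyGrid:
    """Full factorial grid of the simulation study (defaults are the study's).

    ``design_ids`` selects unbalanced designs by their 1..34 number;
    None means all 34.  Every (design, beta3, construction, replicate)
    cell derives its own independent seed stream from ``base_seed``, so
    any single cell is reproducible in isolation.
    """

    beta3_values: tuple[float, ...] = (0.0, 4.0, 8.0)
    constructions: tuple[str, ...] = CONSTRUCTIONS
    replicates: int = 1000
    alpha: float = 0.05
    base_seed: int = 0
    scale: int = 10
    design_ids: tuple[int, ...] | None = None
    beta0: float = 10.0
    beta1: float = 4.0
    beta2: float = 4.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha!r}")

    def designs(self) -> list[tuple[int, DesignCounts]]:
        all_designs = study_designs(self.scale)
        if self.design_ids is None:
            return list(enumerate(all_designs, start=1))
        for i in self.design_ids:
            if not 1 <= i <= 34:
                raise ValueError(f"design id {i} outside 1..34")
        return [(i, all_designs[i - 1]) for i in self.design_ids]

    def spec(self, beta3: float, construction: str) -> EffectSpec:
        return EffectSpec(
            beta0=self.beta0, beta1=self.beta1, beta2=self.beta2,
            beta3=beta3, sigma=self.sigma, construction=construction,
        )


def _nonneg_code(x: float) -> int:
    """Fold a (possibly negative) scalar into a non-negative integer seed word."""
    i = int(round(float(x) * 1_000_000))
    return 2 * i if i >= 0 else -2 * i + 1


def replicate_seed(
    base_seed: int, design_id: int, beta3: float, construction: str, replicate: int
) -> np.random.SeedSequence:
    """Independent, reproducible seed stream for one replicate of one study cell."""
    return np.random.SeedSequence(
        (
            int(base_seed),
            int(design_id),
            _nonneg_code(beta3),
            CONSTRUCTIONS.index(construction),
            int(replicate),
        )
    )


def run_cell(
    design: DesignCounts,
    spec: EffectSpec,
    replicates: int = 1000,
    alpha: float = 0.05,
    base_seed: int = 0,
    design_id: int = 0,
    balanced: DesignCounts | None = None,
    collect_f: bool = False,
) -> pd.DataFrame:
    """Rejection rates of one study cell, tidy: one row per (method, effect).

    Draws ``replicates`` paired samples; the unbalanced sample is
    analysed with Type II and III SS, the balanced counterpart with the
    sequential analysis (all types coincide there).  The returned frame
    carries the fraction of replicates in which the unbalanced
    interaction stayed non-significant — the rate at which the
    "use Type II unless the interaction is significant" rule would pick
    Type II — in ``attrs['ss2_choice_rate']``; with ``collect_f`` the
    per-replicate full-model F statistics are in ``attrs['f_stats']``.
    """
    if balanced is None:
        if design.total % 4:
            raise ValueError(f"N={design.total} has no balanced 2x2 counterpart")
        per_cell = design.total // 4
        balanced = DesignCounts(per_cell, per_cell, per_cell, per_cell)
    rejections = {(m, e): 0 for m in METHODS for e in EFFECTS}
    ss2_choice = 0
    f_stats: dict[tuple[str, str], list[float]] = {
        (m, e): [] for m in METHODS for e in EFFECTS
    }
    for rep in range(replicates):
        seed = replicate_seed(base_seed, design_id, spec.beta3, spec.construction, rep)
        try:
            unb, bal = generate_paired(design, balanced, spec, seed)
            fits_u = nested_fits(unb, coding="contrast")
            fits_b = nested_fits(bal, coding="contrast")
        except Exception as exc:  # noqa: BLE001 - annotate with the replicate index
            raise RuntimeError(f"replicate {rep} of design {design.counts} failed") from exc
        tables = {
            "balanced": ss_type1(fits_b, order="A"),
            "ss2": ss_type2(fits_u),
            "ss3": ss_type3(fits_u),
        }
        for method, table in tables.items():
            rej = f_test(table, alpha)
            for effect in EFFECTS:
                rejections[(method, effect)] += rej[effect]
            if collect_f:
                fs = table.f_stats()
                for effect in EFFECTS:
                    f_stats[(method, effect)].append(fs[effect])
        if not f_test(tables["ss3"], alpha)["AB"]:
            ss2_choice += 1

    rows = []
    for method in METHODS:
        for effect in EFFECTS:
            rate = rejections[(method, effect)] / replicates
            rows.append(
                {
                    "design_id": design_id,
                    "n00": design.n00, "n01": design.n01,
                    "n10": design.n10, "n11": design.n11,
                    "beta3": spec.beta3,
                    "construction": spec.construction,
                    "method": method,
                    "effect": effect,
                    "rate": rate,
                    "mc_se": float(np.sqrt(rate * (1 - rate) / replicates)),
                    "replicates": replicates,
                }
            )
    out = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    out.attrs["ss2_choice_rate"] = ss2_choice / replicates
    if collect_f:
        out.attrs["f_stats"] = {k: np.array(v) for k, v in f_stats.items()}
    return out


def run_study(grid: StudyGrid, progress: bool = False) -> pd.DataFrame:
    """Run every cell of the grid; tidy report, one row per (cell, method, effect)."""
    frames = []
    cells = [
        (design_id, design, beta3, construction)
        for design_id, design in grid.designs()
        for beta3 in grid.beta3_values
        for construction in grid.constructions
    ]
    for k, (design_id, design, beta3, construction) in enumerate(cells):
        if progress:
            print(f"[{k + 1}/{len(cells)}] design {design_id} beta3={beta3} {construction}")
        cell = run_cell(
            design,
            grid.spec(beta3, construction),
            replicates=grid.replicates,
            alpha=grid.alpha,
            base_seed=grid.base_seed,
            design_id=design_id,
        )
        cell = cell.assign(ss2_choice_rate=cell.attrs["ss2_choice_rate"])
        frames.append(cell)
    return pd.concat(frames, ignore_index=True)


def analytic_power(
    design: DesignCounts,
    spec: EffectSpec,
    effect: str = "AB",
    ss_type: str = "III",
    alpha: float = 0.05,
    coding: str = "contrast",
) -> float:
    """Closed-form power of one F test from noncentral-F theory.

    The noncentrality is lambda = SS0 / sigma^2 where SS0 is the SS the
    engine attributes to the effect (under the given type, coding and
    cell counts) when every subject equals its cell mean exactly; the
    power is the upper tail of F(1, N - 4; lambda) beyond the central-F
    critical value.  An effect with zero noise-free SS has power alpha.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}, got {effect!r}")
    means = spec.cell_means()
    a, b = _level_arrays(design)
    exact = SampleData(a=a, b=b, y=np.repeat(means, design.counts), design=design, spec=spec)
    fits = nested_fits(exact, coding=coding)
    kind_table = {
        "I(A)": ss_type1(fits, "A"),
        "I(B)": ss_type1(fits, "B"),
        "II": ss_type2(fits),
        "III": ss_type3(fits),
    }
    ss0 = max(kind_table[_normalize_ss_type(ss_type)].ss[effect], 0.0)
    lam = ss0 / spec.sigma**2
    df_resid = design.total - 4
    crit = stats.f.isf(alpha, 1, df_resid)
    if lam < 1e-12:  # ncf is degenerate at zero noncentrality; the limit is central F
        return float(stats.f.sf(crit, 1, df_resid))
    return float(stats.ncf.sf(crit, 1, df_resid, lam))


def summarize_means(report: pd.DataFrame) -> pd.DataFrame:
    """Mean rejection rate over designs, wide: one row per (construction, beta3).

    Columns ``<method>_<effect>`` average the per-design rates with
    equal weight (the balanced column averages the paired balanced arms,
    which all estimate the same quantity).  If the tidy report carries a
    ``ss2_choice_rate`` column its mean is appended as well.
    """
    wide = (
        report.pivot_table(
            index=["construction", "beta3"],
            columns=["method", "effect"],
            values="rate",
            aggfunc="mean",
        )
        .reindex(columns=pd.MultiIndex.from_product([METHODS, EFFECTS]))
    )
    wide.columns = [f"{m}_{e}" for m, e in wide.columns]
    if "ss2_choice_rate" in report.columns:
        wide["ss2_choice_rate"] = report.groupby(["construction", "beta3"])[
            "ss2_choice_rate"
        ].mean()
    return wide.reset_index()


def compare_to_balanced(report: pd.DataFrame) -> pd.DataFrame:
    """Classify each unbalanced design as higher/lower/tied versus its balanced arm.

    One row per (construction, beta3, method in {ss2, ss3}, effect) with
    the number and percentage of designs whose rejection rate exceeds
    (resp. falls below) the rejection rate of the design's own paired
    balanced arm, and the mean difference Delta within each group (NaN
    when the group is empty).  Exact ties form their own category.
    """
    rates = report.pivot_table(
        index=["construction", "beta3", "design_id", "effect"],
        columns="method",
        values="rate",
    ).reset_index()
    rows = []
    for (construction, beta3, effect), grp in rates.groupby(
        ["construction", "beta3", "effect"], sort=True
    ):
        for method in ("ss2", "ss3"):
            diff = grp[method] - grp["balanced"]
            n = len(diff)
            higher, lower = diff[diff > 0], diff[diff < 0]
            rows.append(
                {
                    "construction": construction,
                    "beta3": beta3,
                    "method": method,
                    "effect": effect,
                    "n_designs": n,
                    "n_higher": len(higher),
                    "pct_higher": 100.0 * len(higher) / n,
                    "delta_higher": higher.mean() if len(higher) else np.nan,
                    "n_lower": len(lower),
                    "pct_lower": 100.0 * len(lower) / n,
                    "delta_lower": lower.mean() if len(lower) else np.nan,
                    "n_tied": n - len(higher) - len(lower),
                }
            )
    return pd.DataFrame(rows)


def coefficient_summary(
    beta0: float = 10.0,
    beta1: float = 4.0,
    beta2: float = 4.0,
    beta3: float = 4.0,
    sigma: float = 10.0,
    n_per_cell: int = 250,
    replicates: int = 1000,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean recovered coefficients and SS on large balanced samples.

    For each effect construction the same simulated samples (balanced,
    ``n_per_cell`` per cell) are analysed under both codings; rows give
    the replicate-mean fitted coefficient and Type II SS per effect.
    A *congruous* pairing (construction codes match the analysis codes)
    recovers the generating betas; an incongruous one redistributes the
    interaction into the main effects and intercept.  The residual row
    reports the mean root mean-square error as its coefficient.
    """
    design = DesignCounts(n_per_cell, n_per_cell, n_per_cell, n_per_cell)
    rows = []
    for c_idx, construction in enumerate(CONSTRUCTIONS):
        spec = EffectSpec(
            beta0=beta0, beta1=beta1, beta2=beta2, beta3=beta3,
            sigma=sigma, construction=construction,
        )
        coef_sums = {coding: np.zeros(4) for coding in ("treatment", "contrast")}
        ss_sums = {coding: np.zeros(3) for coding in ("treatment", "contrast")}
        resid_sums = {coding: np.zeros(2) for coding in ("treatment", "contrast")}
        for rep in range(replicates):
            seed = np.random.SeedSequence((int(base_seed), 1_000_003, c_idx, rep))
            sample = generate_sample(design, spec, seed)
            for coding in ("treatment", "contrast"):
                est = FactorialAnova(coding=coding).fit(sample)
                table = est.anova_table("II")
                coef_sums[coding] += est.coef_
                ss_sums[coding] += [table.ss[e] for e in EFFECTS]
                resid_sums[coding] += [est.residual_ss_, np.sqrt(table.ms_resid)]
        true_beta = {"Intercept": beta0, "A": beta1, "B": beta2, "AB": beta3, "Residual": sigma}
        for coding in ("treatment", "contrast"):
            coefs = coef_sums[coding] / replicates
            ss_mean = ss_sums[coding] / replicates
            for i, effect in enumerate(("Intercept", "A", "B", "AB")):
                rows.append(
                    {
                        "construction": construction,
                        "analysis_coding": coding,
                        "effect": effect,
                        "df": np.nan if effect == "Intercept" else 1,
                        "true_beta": true_beta[effect],
                        "beta_hat": coefs[i],
                        "ss": np.nan if effect == "Intercept" else ss_mean[i - 1],
                    }
                )
            rows.append(
                {
                    "construction": construction,
                    "analysis_coding": coding,
                    "effect": "Residual",
                    "df": 4 * n_per_cell - 4,
                    "true_beta": sigma,
                    "beta_hat": resid_sums[coding][1] / replicates,
                    "ss": resid_sums[coding][0] / replicates,
                }
            )
    return pd.DataFrame(rows)
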