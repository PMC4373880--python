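"""SS engine: hand-computed fits, coding invariances, reparameterization, cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from unbalanced_anova import (
    EffectSpec,
    FactorialAnova,
    RankDeficiencyError,
    SampleData,
    design_matrix,
    f_test,
    generate_sample,
    nested_fits,
    ss_type1,
    ss_type2,
    ss_type3,
    venn_components,
)
from unbalanced_anova.designs import DesignCounts

from conftest import SEED, random_small_sample


def toy_sample(cell_values=(10.0, 14.0, 14.0, 22.0), n_per_cell=2) -> SampleData:
    """Noise-free balanced toy: every subject sits exactly on its cell mean."""
    a = np.repeat([0, 0, 1, 1], n_per_cell)
    b = np.repeat([0, 1, 0, 1], n_per_cell)
    y = np.repeat(cell_values, n_per_cell)
    return SampleData.from_arrays(a, b, y)


def test_nested_fits_on_hand_computed_toy():
    """R(S) of the noise-free (10, 14, 14, 22) toy agrees with hand least squares."""
    fits = nested_fits(toy_sample(), coding="contrast")
    assert fits.r_of("A") == pytest.approx(72.0)
    assert fits.r_of("B") == pytest.approx(72.0)
    assert fits.r_of("A", "B") == pytest.approx(144.0)
    assert fits.r_of("A", "B", "AB") == pytest.approx(152.0)
    assert fits.residual_ss == pytest.approx(0.0, abs=1e-9)
    assert fits.total_ss == pytest.approx(152.0)
    assert fits.df_resid == 4


def test_type3_main_effect_depends_on_coding_on_the_toy():
    """Under (0,1) coding the unique A SS of the toy is 16; under (-1,1) it is 72."""
    sample = toy_sample()
    assert ss_type3(nested_fits(sample, "treatment")).ss["A"] == pytest.approx(16.0)
    assert ss_type3(nested_fits(sample, "contrast")).ss["A"] == pytest.approx(72.0)


def test_venn_components_vanish_on_balanced_contrast_toy():
    """Contrast coding makes the toy orthogonal: only unique parts remain."""
    comps = venn_components(nested_fits(toy_sample(), "contrast"))
    assert comps.t == pytest.approx(72.0)
    assert comps.x == pytest.approx(72.0)
    assert comps.z == pytest.approx(8.0)
    for name in "uvwy":
        assert getattr(comps, name) == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def random_samples():
    rng = np.random.default_rng(SEED)
    return [random_small_sample(rng) for _ in range(30)]


def test_ss_invariances_across_codings(random_samples):
    """Type I and II SS (and the unique interaction z) are coding-invariant; Type III mains are not."""
    for sample in random_samples:
        ft = nested_fits(sample, "treatment")
        fc = nested_fits(sample, "contrast")
        for order in ("A", "B"):
            for e in ("A", "B", "AB"):
                assert ss_type1(ft, order).ss[e] == pytest.approx(ss_type1(fc, order).ss[e])
        for e in ("A", "B", "AB"):
            assert ss_type2(ft).ss[e] == pytest.approx(ss_type2(fc).ss[e])
        assert ss_type3(ft).ss["AB"] == pytest.approx(ss_type3(fc).ss["AB"])
        # z is the interaction SS of every type
        z = venn_components(fc).z
        for table in (ss_type1(fc, "A"), ss_type1(fc, "B"), ss_type2(fc), ss_type3(fc)):
            assert table.ss["AB"] == pytest.approx(z)
    # coding dependence of Type III mains is generic: it holds on a clearly unbalanced sample
    rng = np.random.default_rng(SEED + 1)
    sample = generate_sample(DesignCounts(2, 2, 2, 6), EffectSpec(beta3=4.0), rng)
    assert ss_type3(nested_fits(sample, "treatment")).ss["A"] != pytest.approx(
        ss_type3(nested_fits(sample, "contrast")).ss["A"]
    )


def test_additivity_and_venn_identities(random_samples):
    """Both Type I orders and the seven Venn components sum to the full-model SS."""
    for sample in random_samples:
        for coding in ("treatment", "contrast"):
            fits = nested_fits(sample, coding)
            full = fits.r_of("A", "B", "AB")
            rel = 1e-8 * max(1.0, abs(fits.total_ss))
            for order in ("A", "B"):
                assert sum(ss_type1(fits, order).ss.values()) == pytest.approx(full, abs=rel)
            comps = venn_components(fits)
            assert sum(comps.as_dict().values()) == pytest.approx(full, abs=rel)
            assert comps.t + comps.u + comps.v + comps.w == pytest.approx(fits.r_of("A"), abs=rel)
            assert comps.x + comps.y + comps.u + comps.v == pytest.approx(fits.r_of("B"), abs=rel)
            assert comps.z + comps.w + comps.y + comps.v == pytest.approx(fits.r_of("AB"), abs=rel)
            assert full + fits.residual_ss == pytest.approx(fits.total_ss, abs=rel)
            # nesting monotonicity
            assert fits.r_of("A") <= fits.r_of("A", "B") + rel
            assert fits.r_of("A", "B") <= full + rel


def test_balanced_sample_makes_ss_types_agree(balanced10):
    """Balance makes the factor contrasts orthogonal, so sequential and adjusted SS coincide.

    Type III joins them only under contrast coding, which also makes the
    interaction column orthogonal to the mains; under treatment coding
    the interaction correction still separates Type III.
    """
    sample = generate_sample(balanced10, EffectSpec(beta3=4.0), SEED)
    for coding in ("treatment", "contrast"):
        fits = nested_fits(sample, coding)
        tables = [ss_type1(fits, "A"), ss_type1(fits, "B"), ss_type2(fits)]
        if coding == "contrast":
            tables.append(ss_type3(fits))
        for e in ("A", "B"):
            values = {t.ss[e] for t in tables}
            assert max(values) - min(values) < 1e-7 * fits.total_ss
    # under treatment coding Type III mains stay apart even on balanced data
    ft = nested_fits(sample, "treatment")
    assert abs(ss_type3(ft).ss["A"] - ss_type2(ft).ss["A"]) > 1e-6 * ft.total_ss


def test_coefficient_reparameterization_between_codings(random_samples):
    """Treatment (b) and contrast (c) full-model coefficients obey the exact affine map."""
    for sample in random_samples:
        b = FactorialAnova(coding="treatment").fit(sample).coef_
        c = FactorialAnova(coding="contrast").fit(sample).coef_
        assert c[3] == pytest.approx(b[3] / 4, abs=1e-8)
        assert c[1] == pytest.approx(b[1] / 2 + b[3] / 4, abs=1e-8)
        assert c[2] == pytest.approx(b[2] / 2 + b[3] / 4, abs=1e-8)
        assert c[0] == pytest.approx(b[0] + (b[1] + b[2]) / 2 + b[3] / 4, abs=1e-8)


def test_fitted_cell_means_are_coding_invariant(random_samples):
    """Both codings span the same full-model column space, so fitted cell means agree."""
    from unbalanced_anova.anova import _cell_code_matrix

    for sample in random_samples[:10]:
        fitted = {
            coding: _cell_code_matrix(coding) @ FactorialAnova(coding=coding).fit(sample).coef_
            for coding in ("treatment", "contrast")
        }
        assert fitted["treatment"] == pytest.approx(fitted["contrast"])
        est = FactorialAnova(coding="contrast").fit(sample)
        assert fitted["contrast"] == pytest.approx(est.cell_means_)


def test_statsmodels_anova_lm_cross_check(random_samples):
    """SS I/II/III and the residual match statsmodels under matching contrasts."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    contrast_of = {"treatment": "Treatment", "contrast": "Sum"}
    for sample in random_samples[:6]:
        frame = sample.to_frame()
        for coding, patsy_contrast in contrast_of.items():
            fits = nested_fits(sample, coding)
            formula = (
                f"y ~ C(a, {patsy_contrast}) + C(b, {patsy_contrast}) "
                f"+ C(a, {patsy_contrast}):C(b, {patsy_contrast})"
            )
            model = ols(formula, frame).fit()
            rows = {
                "A": f"C(a, {patsy_contrast})",
                "B": f"C(b, {patsy_contrast})",
                "AB": f"C(a, {patsy_contrast}):C(b, {patsy_contrast})",
            }
            for typ, table in ((1, ss_type1(fits, "A")), (2, ss_type2(fits)), (3, ss_type3(fits))):
                ref = sm.stats.anova_lm(model, typ=typ)
                for effect, row in rows.items():
                    assert table.ss[effect] == pytest.approx(ref.loc[row, "sum_sq"], rel=1e-8)
                assert table.residual_ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-8)


def test_f_test_degenerate_and_p_value_recomputation():
    """Constant outcome gives SS=0, F=0, p=1 and no rejections; p matches an independent F-CDF."""
    sample = toy_sample(cell_values=(5.0, 5.0, 5.0, 5.0), n_per_cell=3)
    fits = nested_fits(sample, "contrast")
    for subset in (("A",), ("B",), ("AB",), ("A", "B"), ("A", "B", "AB")):
        assert fits.r_of(*subset) == pytest.approx(0.0, abs=1e-9)
    # constant y has zero residual too; use a noisy sample for a meaningful F
    noisy = generate_sample(DesignCounts(3, 4, 2, 3), EffectSpec(beta3=4.0), SEED)
    table = ss_type2(nested_fits(noisy, "contrast"))
    for effect, f_stat in table.f_stats().items():
        expected_p = float(special.fdtrc(1.0, float(table.df_resid), f_stat))
        assert table.p_values()[effect] == pytest.approx(expected_p, abs=1e-10)
    rejected = f_test(table, alpha=0.9999999)
    assert all(rejected.values())


def test_rank_errors_and_input_validation():
    a = np.repeat([0, 0, 1], [3, 3, 3])
    b = np.repeat([0, 1, 0], [3, 3, 3])
    with pytest.raises(RankDeficiencyError, match=r"cell \(T, T\)"):
        FactorialAnova().fit(SampleData.from_arrays(a, b, np.arange(9.0)))
    with pytest.raises(ValueError, match="at least 5"):
        FactorialAnova().fit(toy_sample(n_per_cell=1))
    with pytest.raises(ValueError, match="coding"):
        nested_fits(toy_sample(), coding="helmert")
    with pytest.raises(ValueError, match="SS type"):
        FactorialAnova().fit(toy_sample()).anova_table("IV")


def test_estimator_accepts_frames_arrays_and_sklearn_protocol():
    sample = generate_sample(DesignCounts(3, 3, 3, 3), EffectSpec(), SEED)
    ref = FactorialAnova().fit(sample).anova_table("II").ss["A"]
    frame = sample.to_frame()
    assert FactorialAnova().fit(frame).anova_table("II").ss["A"] == pytest.approx(ref)
    X = np.column_stack([sample.a, sample.b])
    assert FactorialAnova().fit(X, sample.y).anova_table("II").ss["A"] == pytest.approx(ref)
    # -1/1 encoded input levels are normalized; the analysis coding stays a parameter
    X_pm = np.column_stack([2 * sample.a - 1, 2 * sample.b - 1])
    assert FactorialAnova().fit(X_pm, sample.y).anova_table("II").ss["A"] == pytest.approx(ref)

    from sklearn.base import clone

    est = FactorialAnova(coding="treatment", alpha=0.01)
    assert est.get_params() == {"coding": "treatment", "alpha": 0.01, "tol": 1e-10}
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    with pytest.raises(AttributeError, match="not fitted"):
        cloned.anova_table()

    matrix = design_matrix(sample, "treatment")
    assert matrix.shape == (len(sample), 4)
    assert np.array_equal(matrix[:, 3], (sample.a * sample.b).astype(float))


def test_anova_table_frame_layout():
    frame = FactorialAnova().fit(toy_sample()).anova_table("3").to_frame()
    assert list(frame["effect"]) == ["A", "B", "AB", "Residual"]
    assert frame.attrs["ss_type"] == "III"
    assert (frame.loc[frame["effect"] != "Residual", "df"] == 1).all()
    assert isinstance(frame, pd.DataFrame)
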