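"""Statistical battery vs closed-form sigma-formula oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import perispace as ps
from perispace.cohort import (
    DegenerateDataError,
    RankDeficiencyError,
    benjamini_hochberg,
)


def _sigma_pearson(x, y):
    """Textbook sum-based product-moment correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx * sx) * (n * syy - sy * sy)
    )


class TestPearson:
    def test_exact_line_gives_r2_one(self):
        x = np.arange(10.0)
        r, r2, p = ps.pearson_r2(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_after_centering_gives_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, r2, _ = ps.pearson_r2(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_ten_point_fixture_matches_sigma_formula(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, 10).tolist()
        y = [2.5 * v + rng.normal(0, 2) for v in x]
        r, r2, _ = ps.pearson_r2(x, y)
        expected = _sigma_pearson(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert r2 == pytest.approx(expected**2, abs=1e-12)

    def test_complete_pairs_only(self):
        x = [1, 2, 3, np.nan, 5]
        y = [2, 4, 6, 8, np.nan]
        r, _, _ = ps.pearson_r2(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            ps.pearson_r2([1, 1, 1, 1], [1, 2, 3, 4])


class TestLinreg:
    def test_exact_line_recovered(self):
        x = np.arange(12.0)
        res = ps.linreg(3 * x - 4, x)
        assert res.slopes["x0"] == pytest.approx(3.0)
        assert res.intercept == pytest.approx(-4.0)
        assert res.r2 == pytest.approx(1.0)

    def test_simple_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 20, 20)
        y = 1.4 * x + rng.normal(0, 5, 20)
        res = ps.linreg(y, x)
        _, r2, _ = ps.pearson_r2(x, y)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_three_predictor_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(31)
        theta = rng.uniform(10, 170, 20)
        vol = rng.uniform(4, 20, 20)
        tv = theta * vol / 1000 + rng.normal(0, 0.3, 20)  # break exact product
        y = 3500 - 4 * theta - 20 * vol - 100 * tv + rng.normal(0, 40, 20)
        X = pd.DataFrame({"theta": theta, "vol": vol, "tv": tv})
        res = ps.linreg(y, X)
        # explicit (X'X)^-1 X'y with an intercept column
        D = np.column_stack([np.ones(20), theta, vol, tv])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert res.intercept == pytest.approx(beta[0], rel=1e-9)
        assert res.slopes["theta"] == pytest.approx(beta[1], rel=1e-9)
        assert res.slopes["vol"] == pytest.approx(beta[2], rel=1e-9)
        assert res.slopes["tv"] == pytest.approx(beta[3], rel=1e-9)

    def test_standardized_fit_preserves_r2_f_t(self):
        rng = np.random.default_rng(37)
        X = pd.DataFrame(rng.uniform(0, 10, size=(18, 2)), columns=["a", "b"])
        y = 2 * X["a"] - 3 * X["b"] + rng.normal(0, 1, 18)
        raw = ps.linreg(y, X, standardized=False)
        std = ps.linreg(y, X, standardized=True)
        assert std.r2 == pytest.approx(raw.r2, abs=1e-10)
        assert std.f_stat == pytest.approx(raw.f_stat, rel=1e-9)
        for k in ("a", "b"):
            assert std.t_stats[k] == pytest.approx(raw.t_stats[k], rel=1e-9)
            assert std.standardized_betas[k] == pytest.approx(
                raw.standardized_betas[k], rel=1e-9
            )

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(41)
        a = rng.uniform(0, 1, 15)
        b = rng.uniform(0, 1, 15)
        X = pd.DataFrame({"a": a, "b": b, "c": a + 2 * b})
        with pytest.raises(RankDeficiencyError) as err:
            ps.linreg(rng.uniform(0, 1, 15), X)
        assert "c" in str(err.value)


class TestTwoSampleT:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, df, p = ps.two_sample_t(a, list(a))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_p_tiny(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        _, _, p = ps.two_sample_t(a, b)
        assert p < 1e-10

    def test_fixture_matches_pooled_formula(self):
        a = [12.1, 9.8, 11.4, 10.2, 12.9]
        b = [8.1, 7.4, 9.5, 8.8]
        t, df, _ = ps.two_sample_t(a, b)
        na, nb = len(a), len(b)
        ma, mb = sum(a) / na, sum(b) / nb
        va = sum((v - ma) ** 2 for v in a) / (na - 1)
        vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_hand = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == na + nb - 2

    def test_welch_option_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(43)
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(1, 5.0, 5)
        t_pooled, df_pooled, _ = ps.two_sample_t(a, b, pooled=True)
        t_welch, df_welch, _ = ps.two_sample_t(a, b, pooled=False)
        assert df_welch != df_pooled

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateDataError):
            ps.two_sample_t([2.0, 2.0, 2.0], [2.0, 2.0])


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            _, p = ps.shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 90

    def test_exponential_samples_usually_rejected(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(1.0, 50)
            _, p = ps.shapiro_wilk(x)
            hits += p < 0.05
        assert hits >= 90

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateDataError):
            ps.shapiro_wilk([3.0] * 10)


def _synthetic_cohort(n=20, seed=2, planted=True):
    """Hand-built cohort table with a planted placement-dose link."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(5, 175, n)
    vol = rng.uniform(4, 20, n)
    score = (theta / 180) * (vol / 20)
    noise = rng.normal(0, 120, n)
    rdmax1 = 3500 - (1400 * score if planted else 0) + noise
    peri = 2 + 11 * score + rng.normal(0, 1, n)
    cats = ["SYM1"] * (n - 4) + ["MISSING_INF"] * 2 + ["SYM2"] * 2
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "theta_deg": theta,
            "gel_volume_cc": vol,
            "norm_theta_vol": score,
            "peri_center_mm": peri,
            "peri_inf1_mm": peri * 0.8 + rng.normal(0, 1.5, n),
            "peri_inf2_mm": peri * 0.6 + rng.normal(0, 2.0, n),
            "rdmax_1cc_cgy": rdmax1,
            "rdmax_2cc_cgy": rdmax1 - 60,
            "rdmax_3cc_cgy": rdmax1 - 110,
            "rv95_cc": np.clip(5 - 4.5 * score + rng.normal(0, 0.7, n), 0, None),
            "rv90_cc": np.clip(7 - 5.5 * score + rng.normal(0, 0.7, n), 0, None),
            "rv80_cc": np.clip(10 - 6.5 * score + rng.normal(0, 0.7, n), 0, None),
            "symmetry_category": cats,
            "toxicity_grade": (rdmax1 > np.median(rdmax1)).astype(int),
        }
    )


class TestAnalysisBattery:
    def test_planted_interaction_outranks_volume(self):
        report = ps.analysis_battery(_synthetic_cohort())
        g = report.r2_grid["rdmax_1cc_cgy"]
        assert g["norm_theta_vol"] > g["gel_volume_cc"]
        assert report.r2_grid.shape == (6, 6)
        assert report.multivariable is not None
        assert 0 <= report.multivariable.r2 <= 1

    def test_symmetry_and_toxicity_sections_present(self):
        report = ps.analysis_battery(_synthetic_cohort())
        assert set(report.symmetry_tests["group"]) <= {"MISSING_INF", "SYM2"}
        assert len(report.toxicity_comparison) == 2
        tox = report.toxicity_comparison.set_index("metric")
        assert (
            tox.loc["rdmax_1cc_cgy", "mean_toxicity"]
            > tox.loc["rdmax_1cc_cgy", "mean_no_toxicity"]
        )

    def test_identical_patients_reported_degenerate_not_raised(self):
        df = _synthetic_cohort(n=6)
        for col in df.columns:
            if col not in ("patient_id", "symmetry_category"):
                df[col] = df[col].iloc[0]
        report = ps.analysis_battery(df)
        assert report.r2_grid.isna().all().all()
        assert report.notes  # degeneracy is surfaced

    def test_permutation_null_keeps_r2_small(self):
        df = _synthetic_cohort(planted=False, seed=7)
        rng = np.random.default_rng(99)
        r2s = []
        x = df["norm_theta_vol"].to_numpy()
        y = df["rdmax_1cc_cgy"].to_numpy()
        for _ in range(200):
            _, r2, _ = ps.pearson_r2(x, rng.permutation(y))
            r2s.append(r2)
        assert np.quantile(r2s, 0.95) < 0.35

    def test_missing_columns_named(self):
        df = _synthetic_cohort().drop(columns=["rv80_cc", "theta_deg"])
        with pytest.raises(KeyError) as err:
            ps.analysis_battery(df)
        assert "rv80_cc" in str(err.value) and "theta_deg" in str(err.value)


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.2, 0.8])
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0).all()
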