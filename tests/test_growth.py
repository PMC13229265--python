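"""Repeated-measures ANOVA, paired t, growth models and the person bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crewnet import growth
from crewnet.io import WAVES


def panel_from_matrix(X, outcome="y", waves=WAVES):
    """persons x waves matrix -> tidy panel (NaN cells dropped)."""
    rows = []
    for p, row in enumerate(np.asarray(X, dtype=float)):
        for w, v in zip(waves, row):
            if not np.isnan(v):
                rows.append((f"P{p}", w, outcome, v))
    return pd.DataFrame(rows, columns=["person_id", "wave", "outcome", "score"])


def rm_anova_oracle(X):
    """Brute-force within-subject sums-of-squares decomposition."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = X.mean()
    ss_time = n * sum((X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_no_time_effect_gives_zero_F(self):
        X = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 4))
        res = growth.rm_anova(panel_from_matrix(X), "y")
        assert res.F == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("n,df_den", [(9, 24), (10, 27)])
    def test_degrees_of_freedom(self, n, df_den):
        rng = np.random.default_rng(n)
        res = growth.rm_anova(panel_from_matrix(rng.normal(size=(n, 4))), "y")
        assert (res.df_num, res.df_den) == (3, df_den)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(5, 4))
            res = growth.rm_anova(panel_from_matrix(X), "y")
            assert res.F == pytest.approx(rm_anova_oracle(X), rel=1e-10)

    def test_listwise_deletion(self):
        X = np.vstack([np.random.default_rng(1).normal(size=(5, 4))])
        panel = panel_from_matrix(X)
        panel = panel[~((panel["person_id"] == "P0") & (panel["wave"] == "M9"))]
        res = growth.rm_anova(panel, "y")
        assert res.n_complete == 4

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=5))
    def test_invariant_to_person_constants(self, shifts):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        base = growth.rm_anova(panel_from_matrix(X), "y").F
        shifted = X + np.asarray(shifts)[:, None]
        assert growth.rm_anova(panel_from_matrix(shifted), "y").F == pytest.approx(
            base, rel=1e-9
        )

    def test_too_few_complete_cases(self):
        with pytest.raises(ValueError, match="y"):
            growth.rm_anova(panel_from_matrix(np.ones((2, 4))), "y")


class TestPairedT:
    def test_identical_waves(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        X[:, 2] = X[:, 1]
        t, df, p = growth.paired_t(panel_from_matrix(X), "y", "M3", "M6")
        assert t == 0.0 and p == 1.0

    def test_df_with_twelve_pairs(self):
        X = np.random.default_rng(0).normal(size=(12, 4))
        _, df, _ = growth.paired_t(panel_from_matrix(X), "y", "M3", "M6")
        assert df == 11

    def test_hand_computed_toy(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2 * sqrt(3)
        X = np.zeros((3, 4))
        X[:, 1] = [11.0, 12.0, 13.0]
        X[:, 2] = [10.0, 10.0, 10.0]
        t, df, _ = growth.paired_t(panel_from_matrix(X), "y", "M3", "M6")
        assert df == 2
        assert t == pytest.approx(2 * np.sqrt(3))

    def test_antisymmetry(self):
        X = np.random.default_rng(4).normal(size=(8, 4))
        t_ab, _, p_ab = growth.paired_t(panel_from_matrix(X), "y", "M1", "M9")
        t_ba, _, p_ba = growth.paired_t(panel_from_matrix(X), "y", "M9", "M1")
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_one_sided_halves_p(self):
        X = np.random.default_rng(4).normal(size=(8, 4))
        _, _, p2 = growth.paired_t(panel_from_matrix(X), "y", "M1", "M9", tail="two")
        _, _, p1 = growth.paired_t(panel_from_matrix(X), "y", "M1", "M9", tail="one")
        assert p1 == pytest.approx(p2 / 2)


def make_growth_panel(rng, n=12, beta0=50.0, beta1=2.0, sd_i=5.0, sd_s=0.5, sd_e=3.0):
    t = np.arange(4.0)
    rows = []
    for p in range(n):
        u0, u1 = rng.normal(0, sd_i), rng.normal(0, sd_s)
        y = beta0 + u0 + (beta1 + u1) * t + rng.normal(0, sd_e, size=4)
        rows += [(f"P{p}", w, "y", y[k]) for k, w in enumerate(WAVES)]
    return pd.DataFrame(rows, columns=["person_id", "wave", "outcome", "score"])


class TestFitGrowth:
    def test_noise_free_recovers_slope_exactly(self):
        t = np.arange(4.0)
        X = np.vstack([10 + 1.7 * t, 20 + 1.7 * t, 5 + 1.7 * t])
        fit = growth.fit_growth(panel_from_matrix(X), "y")
        assert fit.slope_estimate == pytest.approx(1.7)
        assert fit.slope_p == pytest.approx(0.0, abs=1e-12)

    def test_balanced_closed_form_equals_mean_person_slope(self):
        rng = np.random.default_rng(8)
        panel = make_growth_panel(rng)
        fit = growth.fit_growth(panel, "y", engine="balanced")
        slopes = [
            np.polyfit(np.arange(4.0), sub.sort_values("wave", key=lambda s: s.map(
                {w: k for k, w in enumerate(WAVES)}))["score"].to_numpy(), 1)[0]
            for _, sub in panel.groupby("person_id")
        ]
        assert fit.slope_estimate == pytest.approx(np.mean(slopes))

    def test_mixedlm_agrees_with_closed_form_on_balanced_panel(self):
        rng = np.random.default_rng(9)
        panel = make_growth_panel(rng)
        closed = growth.fit_growth(panel, "y", engine="balanced")
        ml = growth.fit_growth(panel, "y", engine="mixedlm")
        assert ml.slope_estimate == pytest.approx(closed.slope_estimate, abs=1e-5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        panel = make_growth_panel(rng)
        base = growth.fit_growth(panel, "y").slope_estimate
        scaled = panel.assign(score=panel["score"] * 3.5)
        assert growth.fit_growth(scaled, "y").slope_estimate == pytest.approx(3.5 * base)

    def test_month_time_coding_rescales_slope(self):
        t = np.arange(4.0)
        X = np.vstack([10 + 2.0 * t, 30 + 2.0 * t, 50 + 2.0 * t])
        by_wave = growth.fit_growth(panel_from_matrix(X), "y", time_coding="wave_index")
        by_month = growth.fit_growth(panel_from_matrix(X), "y", time_coding="month")
        assert by_wave.slope_estimate == pytest.approx(2.0)
        # months 0,2,5,8 are not equally spaced; noise-free linear-in-wave data
        # fitted on months still slopes upward but shallower
        assert 0 < by_month.slope_estimate < by_wave.slope_estimate

    def test_unbalanced_panel_uses_mixedlm(self):
        rng = np.random.default_rng(12)
        panel = make_growth_panel(rng)
        panel = panel[~((panel["person_id"] == "P0") & (panel["wave"] == "M9"))]
        fit = growth.fit_growth(panel, "y")
        assert fit.engine == "mixedlm"
        assert fit.n_observations == 47


class TestBootstrap:
    def test_noise_free_interval_degenerate(self):
        t = np.arange(4.0)
        X = np.vstack([10 + 2.0 * t, 30 + 2.0 * t, 50 + 2.0 * t, 5 + 2.0 * t])
        lo, hi = growth.bootstrap_ci(panel_from_matrix(X), "y", B=200, seed=0)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(13)
        panel = make_growth_panel(rng)
        a = growth.bootstrap_ci(panel, "y", B=300, seed=42)
        b = growth.bootstrap_ci(panel, "y", B=300, seed=42)
        assert a == b

    def test_interval_shrinks_with_noise(self):
        rng = np.random.default_rng(14)
        wide_noise = make_growth_panel(rng, sd_e=6.0, sd_s=1.0)
        narrow_noise = make_growth_panel(rng, sd_e=0.2, sd_s=0.02)
        lo_w, hi_w = growth.bootstrap_ci(wide_noise, "y", B=400, seed=1)
        lo_n, hi_n = growth.bootstrap_ci(narrow_noise, "y", B=400, seed=1)
        assert (hi_n - lo_n) < (hi_w - lo_w)

    def test_unbalanced_bootstrap_runs(self):
        rng = np.random.default_rng(15)
        panel = make_growth_panel(rng, n=8)
        panel = panel[~((panel["person_id"] == "P0") & (panel["wave"] == "M9"))]
        lo, hi = growth.bootstrap_ci(panel, "y", B=100, seed=2)
        assert lo < hi


class TestSensitivityExclude:
    def test_removes_person(self):
        panel = make_growth_panel(np.random.default_rng(16))
        out = growth.sensitivity_exclude(panel, "P0")
        assert set(out["person_id"]) == {f"P{k}" for k in range(1, 12)}

    def test_exclude_then_restore_is_identity(self):
        panel = make_growth_panel(np.random.default_rng(17))
        out = growth.sensitivity_exclude(panel, "P3")
        restored = (
            pd.concat([out, panel[panel["person_id"] == "P3"]])
            .sort_values(["person_id", "wave"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            restored, panel.sort_values(["person_id", "wave"]).reset_index(drop=True)
        )

    def test_unknown_person_errors(self):
        panel = make_growth_panel(np.random.default_rng(18))
        with pytest.raises(KeyError):
            growth.sensitivity_exclude(panel, "nobody")
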