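import numpy as np
import pandas as pd
import pytest

from troutmorph.mvstats import (
    dfa_loo,
    mancova_interaction,
    manova_wilks,
    repeated_measures_family_means,
)


def make_groups(rng, n_per=30, p=4, shifts=(0.0, 0.0, 0.0)):
    Y, g = [], []
    for i, s in enumerate(shifts):
        block = rng.normal(0, 1, (n_per, p))
        block[:, 0] += s
        Y.append(block)
        g += [f"g{i}"] * n_per
    return np.vstack(Y), np.array(g)


class TestManovaWilks:
    def test_identical_groups_lambda_one(self):
        rng = np.random.default_rng(0)
        block = rng.normal(0, 1, (20, 3))
        Y = np.vstack([block, block])
        g = np.array(["a"] * 20 + ["b"] * 20)
        res = manova_wilks(Y, g)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_univariate_reduces_to_anova_F(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(1)
        Y, g = make_groups(rng, p=1, shifts=(0.0, 0.8, -0.4))
        res = manova_wilks(Y, g)
        F, p = f_oneway(*[Y[g == lab, 0] for lab in np.unique(g)])
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_eigenvalue_identity_oracle(self):
        """Wilks' lambda equals prod 1/(1+lam_i) over eigenvalues of W^-1 B."""
        rng = np.random.default_rng(2)
        Y, g = make_groups(rng, p=5, shifts=(0.0, 0.5, 1.0))
        res = manova_wilks(Y, g)
        labels = np.unique(g)
        grand = Y.mean(axis=0)
        W = sum((Y[g == lab] - Y[g == lab].mean(0)).T @ (Y[g == lab] - Y[g == lab].mean(0))
                for lab in labels)
        B = sum((g == lab).sum() * np.outer(Y[g == lab].mean(0) - grand,
                                            Y[g == lab].mean(0) - grand)
                for lab in labels)
        lam = np.linalg.eigvals(np.linalg.solve(W, B)).real
        assert res.wilks_lambda == pytest.approx(float(np.prod(1 / (1 + lam))), rel=1e-10)

    def test_matches_statsmodels(self):
        """Cross-check Wilks' lambda, F, and p against statsmodels MANOVA."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(3)
        Y, g = make_groups(rng, p=3, shifts=(0.0, 0.6, 0.2))
        res = manova_wilks(Y, g)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = g
        sm = MANOVA.from_formula("y1 + y2 + y3 ~ C(g)", data=df)
        tab = sm.mv_test().results["C(g)"]["stat"]
        assert res.wilks_lambda == pytest.approx(tab.loc["Wilks' lambda", "Value"], rel=1e-8)
        assert res.F == pytest.approx(tab.loc["Wilks' lambda", "F Value"], rel=1e-6)
        assert res.p == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_lambda_invariant_under_linear_transform(self):
        rng = np.random.default_rng(4)
        Y, g = make_groups(rng, p=4, shifts=(0.0, 0.7, 0.3))
        T = rng.normal(0, 1, (4, 4)) + 4 * np.eye(4)
        res1 = manova_wilks(Y, g)
        res2 = manova_wilks(Y @ T, g)
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, rel=1e-8)

    def test_small_group_rejected(self):
        Y = np.random.default_rng(5).normal(size=(11, 2))
        g = np.array(["a"] * 10 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            manova_wilks(Y, g)


class TestMancovaInteraction:
    def _simulate(self, rng, slopes, n_per=40, p=3):
        Y, g, x = [], [], []
        for i, slope in enumerate(slopes):
            xi = rng.uniform(-1, 1, n_per)
            block = rng.normal(0, 1, (n_per, p)) + np.outer(xi, slope)
            Y.append(block)
            x.append(xi)
            g += [f"g{i}"] * n_per
        return np.vstack(Y), np.array(g), np.concatenate(x)

    def test_null_calibration_quick(self):
        """Identical allometric slopes: interaction p-values roughly uniform
        (rejection rate near 5% at alpha = 0.05; full-scale check lives in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        slope = np.array([1.0, 0.5, 0.0])
        rejections = 0
        for _ in range(40):
            Y, g, x = self._simulate(rng, [slope] * 3)
            rejections += mancova_interaction(Y, g, x).p < 0.05
        assert rejections <= 8

    def test_power_against_tripled_slope(self):
        rng = np.random.default_rng(7)
        slope = np.array([1.0, 0.5, 0.0])
        hits = sum(
            mancova_interaction(*self._simulate(rng, [slope, slope, 3 * slope])).p < 0.05
            for _ in range(20)
        )
        assert hits >= 18

    def test_single_group_rejected(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 3))
        with pytest.raises(ValueError, match="single group"):
            mancova_interaction(Y, np.array(["a"] * 30), rng.uniform(size=30))

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(9)
        Y, g, x = self._simulate(rng, [np.zeros(3)] * 2)
        with pytest.raises(ValueError, match="constant"):
            mancova_interaction(Y, g, np.zeros_like(x))


class TestDfaLoo:
    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(10)
        Y, g = make_groups(rng, shifts=(0.0, 1.0, 2.0))
        mat = dfa_loo(Y, g)
        assert np.allclose(mat.sum(axis=1), 100.0)

    def test_separated_groups_high_diagonal(self):
        rng = np.random.default_rng(11)
        Y, g = make_groups(rng, shifts=(0.0, 10.0, 20.0))
        mat = dfa_loo(Y, g)
        assert np.diag(mat.values).min() >= 95.0

    def test_identical_groups_near_chance(self):
        """Three indistinguishable groups reclassify at about 33%."""
        diags = []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            Y, g = make_groups(rng, n_per=30, shifts=(0.0, 0.0, 0.0))
            mat = dfa_loo(Y, g)
            diags.append(np.diag(mat.values).mean())
        assert abs(np.mean(diags) - 100 / 3) < 7.0

    def test_family_subsample_seeded(self):
        rng = np.random.default_rng(12)
        Y, g = make_groups(rng, n_per=30, shifts=(0.0, 1.5, 3.0))
        fam = np.array([f"{gi}_fam{j % 5}" for j, gi in enumerate(g)])
        m1 = dfa_loo(Y, g, families=fam, per_family_subsample=4, seed=99)
        m2 = dfa_loo(Y, g, families=fam, per_family_subsample=4, seed=99)
        pd.testing.assert_frame_equal(m1, m2)
        with pytest.raises(ValueError, match="seed"):
            dfa_loo(Y, g, families=fam, per_family_subsample=4)

    def test_loo_not_better_than_resubstitution(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(13)
        Y, g = make_groups(rng, n_per=25, shifts=(0.0, 0.8, 1.6))
        loo = np.diag(dfa_loo(Y, g).values).mean()
        lda = LinearDiscriminantAnalysis(priors=np.full(3, 1 / 3)).fit(Y, g)
        resub = 100.0 * np.mean(lda.predict(Y) == g)
        assert loo <= resub + 5.0


class TestRepeatedMeasures:
    def _family_data(self, rng, n_fam=12, periods=3, time_trend=0.0,
                     strain_shift=0.0, interaction=0.0):
        rows = []
        for f in range(n_fam):
            strain = "A" if f < n_fam // 2 else "B"
            base = rng.normal(0, 1)
            for t in range(1, periods + 1):
                mu = base + time_trend * t
                if strain == "B":
                    mu += strain_shift + interaction * t
                for _ in range(3):
                    rows.append({"family": f"f{f}", "strain": strain, "period": t,
                                 "score": mu + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_time_trend_detected(self):
        rng = np.random.default_rng(14)
        df = self._family_data(rng, time_trend=1.0)
        tab = repeated_measures_family_means(df, "score").set_index("effect")
        assert tab.loc["period", "p"] < 0.001
        assert tab.loc["strain:period", "p"] > 0.01

    def test_interaction_detected(self):
        rng = np.random.default_rng(15)
        df = self._family_data(rng, interaction=1.5)
        tab = repeated_measures_family_means(df, "score").set_index("effect")
        assert tab.loc["strain:period", "p"] < 0.01

    def test_null_rates_quick(self):
        rng = np.random.default_rng(16)
        ps = {"strain": [], "period": [], "strain:period": []}
        for _ in range(30):
            tab = repeated_measures_family_means(
                self._family_data(rng), "score").set_index("effect")
            for k in ps:
                ps[k].append(tab.loc[k, "p"])
        for k, vals in ps.items():
            assert np.mean(np.array(vals) < 0.05) <= 0.2, k

    def test_family_with_single_period_dropped(self):
        rng = np.random.default_rng(17)
        df = self._family_data(rng)
        df = df[~((df.family == "f0") & (df.period > 1))]
        with pytest.warns(UserWarning, match="f0"):
            tab = repeated_measures_family_means(df, "score")
        assert set(tab["effect"]) == {"strain", "period", "strain:period"}

    def test_single_family_rejected(self):
        rng = np.random.default_rng(18)
        df = self._family_data(rng, n_fam=1)
        with pytest.raises(ValueError):
            repeated_measures_family_means(df, "score")
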