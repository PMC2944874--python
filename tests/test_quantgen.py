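import numpy as np
import pandas as pd
import pytest

from troutmorph.pedigree import (
    IndividualRecord,
    additive_relationship_matrix,
    pedigree_from_design,
    siskiwit_design,
)
from troutmorph.quantgen import (
    AnimalModelREML,
    genetic_correlation,
    lrt_component,
    reml_fit,
    reml_loglik,
    strain_comparison,
)
from troutmorph.simulate import simulate_breeding_values


def brute_force_restricted_loglik(y, X, V):
    """Independent oracle: REML loglik from orthonormal error contrasts,
    L = -1/2 [ (n-p) log 2pi + log|K'VK| + y'K (K'VK)^-1 K'y ]
    with K an orthonormal basis of the null space of X'."""
    n, p = X.shape
    q, _ = np.linalg.qr(np.column_stack([X, np.eye(n)]))
    K = q[:, p:n]
    KVK = K.T @ V @ K
    Ky = K.T @ y
    return -0.5 * ((n - p) * np.log(2 * np.pi)
                   + np.linalg.slogdet(KVK)[1]
                   + Ky @ np.linalg.solve(KVK, Ky))


@pytest.fixture(scope="module")
def toy5():
    """Five-individual pedigree: two founders and three full-sib offspring."""
    ped = [IndividualRecord("s"), IndividualRecord("d")] + [
        IndividualRecord(f"o{i}", sire="s", dam="d") for i in range(3)
    ]
    A = additive_relationship_matrix(ped).values
    rng = np.random.default_rng(11)
    y = rng.normal(0, 1, 5)
    X = np.ones((5, 1))
    return y, X, A


class TestRemlLoglik:
    @pytest.mark.parametrize("va, ve", [(0.7, 0.4), (0.01, 1.5), (2.0, 0.05)])
    def test_matches_brute_force_oracle(self, toy5, va, ve):
        y, X, A = toy5
        V = va * A + ve * np.eye(5)
        assert reml_loglik(y, X, V) == pytest.approx(
            brute_force_restricted_loglik(y, X, V), abs=1e-8)

    def test_oracle_with_covariate_design(self, toy5):
        y, _, A = toy5
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        V = 0.5 * A + 0.8 * np.eye(5)
        assert reml_loglik(y, X, V) == pytest.approx(
            brute_force_restricted_loglik(y, X, V), abs=1e-8)


class TestAnimalModelFit:
    def test_pure_noise_boundary(self, assinica):
        """Trait = fixed mean + iid noise: V_a pinned at the boundary and the
        full loglik equals the reduced (residual-only) loglik."""
        rng = np.random.default_rng(2)
        y = 5.0 + rng.normal(0, 1, assinica["n"])
        full = reml_fit(y, relationship=assinica["A"])
        red = reml_fit(y, relationship=None, random_terms=())
        assert full.varcomp_["additive"] == 0.0
        assert full.h2_ == 0.0
        assert full.loglik_ == pytest.approx(red.loglik_, abs=1e-3)
        lrt = lrt_component(full, red)
        assert lrt.statistic == pytest.approx(0.0, abs=2e-3)
        assert lrt.p > 0.9

    def test_h2_transformation_invariance(self, assinica):
        """Translating or rescaling the trait leaves h2 unchanged (variance
        components scale by c^2)."""
        rng = np.random.default_rng(3)
        bv = simulate_breeding_values(assinica["A"], 0.5, rng)
        y = bv + rng.normal(0, np.sqrt(0.5), assinica["n"])
        f0 = reml_fit(y, relationship=assinica["A"], compute_se=False)
        f1 = reml_fit(y + 100.0, relationship=assinica["A"], compute_se=False)
        f2 = reml_fit(y * 7.0, relationship=assinica["A"], compute_se=False)
        assert f1.h2_ == pytest.approx(f0.h2_, abs=1e-6)
        assert f2.h2_ == pytest.approx(f0.h2_, abs=1e-6)
        assert f2.varcomp_["additive"] == pytest.approx(
            49.0 * f0.varcomp_["additive"], rel=1e-3)

    def test_identity_A_matches_anova_intraclass(self, assinica):
        """With A = I on sire groups, the sire-model h2-analogue equals the
        one-way ANOVA intraclass correlation within Monte-Carlo tolerance."""
        rng = np.random.default_rng(4)
        sire = assinica["sire"]
        codes, uq = pd.factorize(sire)
        effects = rng.normal(0, np.sqrt(0.3), len(uq))
        y = effects[codes] + rng.normal(0, np.sqrt(0.7), assinica["n"])
        fit = reml_fit(y, random_terms=("sire",), sire=sire, compute_se=False)
        t_reml = fit.varcomp_["sire"] / (fit.varcomp_["sire"] + fit.varcomp_["residual"])
        # balanced one-way ANOVA estimator of the intraclass correlation
        df = pd.DataFrame({"y": y, "g": codes})
        k = df.groupby("g").size().iloc[0]
        msb = df.groupby("g")["y"].mean().var(ddof=1) * k
        msw = df.groupby("g")["y"].apply(lambda s: s.var(ddof=1)).mean()
        t_anova = (msb - msw) / (msb + (k - 1) * msw)
        assert t_reml == pytest.approx(t_anova, abs=0.02)

    def test_singular_fixed_design_names_column(self, assinica):
        y = np.arange(assinica["n"], dtype=float)
        X = np.column_stack([np.ones(assinica["n"]), np.ones(assinica["n"])])
        with pytest.raises(ValueError, match="aliased"):
            reml_fit(y, X, relationship=assinica["A"],
                     feature_names=["intercept", "dup"])

    def test_confounded_family_term_refused(self):
        """Nested design without split egg lots: family coincides with dam, so
        the family variance cannot be separated and the term is refused."""
        ped = pedigree_from_design(siskiwit_design(), 4)
        rel = additive_relationship_matrix(ped)
        off = [r for r in ped if r.sire is not None]
        A = rel.subset([r.id for r in off]).values
        dam = np.array([r.dam for r in off])
        fam = np.array([f"{r.sire}x{r.dam}" for r in off])
        y = np.random.default_rng(5).normal(0, 1, len(off))
        with pytest.raises(ValueError, match="confounded"):
            reml_fit(y, relationship=A, dam=dam, family=fam,
                     random_terms=("additive", "dam", "family"))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = AnimalModelREML(random_terms=("additive", "dam"), n_restarts=2)
        assert clone(est).get_params() == est.get_params()


class TestLRT:
    def test_quantile_anchor(self, assinica):
        rng = np.random.default_rng(6)
        bv = simulate_breeding_values(assinica["A"], 0.6, rng)
        y = bv + rng.normal(0, 0.7, assinica["n"])
        full = reml_fit(y, relationship=assinica["A"], compute_se=False)
        red = reml_fit(y, random_terms=())
        lrt = lrt_component(full, red)
        assert lrt.statistic >= 0
        assert 0 <= lrt.p <= 1
        # chi2(1): statistic 3.84 ~ p 0.05
        from scipy.stats import chi2
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_power_at_h2_half(self, assinica):
        """h2 = 0.5 on the 30-family design: the additive LRT is significant
        (p < 0.05) in the clear majority of replicates."""
        ps = []
        for seed in range(12):
            rng = np.random.default_rng(200 + seed)
            bv = simulate_breeding_values(assinica["A"], 0.5, rng)
            y = bv + rng.normal(0, np.sqrt(0.5), assinica["n"])
            full = reml_fit(y, relationship=assinica["A"], compute_se=False)
            red = reml_fit(y, random_terms=())
            ps.append(lrt_component(full, red).p)
        assert np.median(ps) < 0.05

    def test_non_nested_rejected(self, assinica):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, assinica["n"])
        a = reml_fit(y, relationship=assinica["A"])
        b = reml_fit(y, random_terms=("dam",), dam=assinica["dam"])
        with pytest.raises(ValueError, match="nest|drop"):
            lrt_component(a, b)

    def test_boundary_mixture_halves_p(self, assinica):
        rng = np.random.default_rng(8)
        bv = simulate_breeding_values(assinica["A"], 0.4, rng)
        y = bv + rng.normal(0, 0.8, assinica["n"])
        full = reml_fit(y, relationship=assinica["A"], compute_se=False)
        red = reml_fit(y, random_terms=())
        plain = lrt_component(full, red, boundary_correction=False)
        mixed = lrt_component(full, red, boundary_correction=True)
        if plain.statistic > 0:
            assert mixed.p == pytest.approx(plain.p / 2)


class TestGeneticCorrelation:
    def test_shared_breeding_values_give_rg_one(self, assinica):
        rng = np.random.default_rng(9)
        bv = simulate_breeding_values(assinica["A"], 0.6, rng)
        y1 = bv + rng.normal(0, 0.5, assinica["n"])
        y2 = bv + rng.normal(0, 0.5, assinica["n"])
        res = genetic_correlation(y1, y2, relationship=assinica["A"], compute_se=False)
        assert res.r_g > 0.8
        assert res.lrt.p < 0.01

    def test_independent_breeding_values_near_zero(self, assinica):
        rgs = []
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            b1 = simulate_breeding_values(assinica["A"], 0.5, rng)
            b2 = simulate_breeding_values(assinica["A"], 0.5, rng)
            y1 = b1 + rng.normal(0, np.sqrt(0.5), assinica["n"])
            y2 = b2 + rng.normal(0, np.sqrt(0.5), assinica["n"])
            res = genetic_correlation(y1, y2, relationship=assinica["A"],
                                      compute_se=False)
            rgs.append(res.r_g)
        assert abs(np.mean(rgs)) < 0.25

    def test_mismatched_lengths_rejected(self, assinica):
        with pytest.raises(ValueError, match="same individuals"):
            genetic_correlation(np.zeros(10), np.zeros(11), relationship=assinica["A"])


class TestStrainComparison:
    @pytest.fixture()
    def two_strains(self, assinica):
        rng = np.random.default_rng(10)
        n = assinica["n"]
        half = n // 2
        return pd.DataFrame({
            "y": rng.normal(0, 1, n),
            "strain": ["A"] * half + ["B"] * (n - half),
            "sire": assinica["sire"], "dam": assinica["dam"],
            "mature": rng.random(n) < 0.2,
        })

    def test_zero_noise_identical_strains(self, assinica):
        n = assinica["n"]
        df = pd.DataFrame({
            "y": np.ones(n), "strain": ["A", "B"] * (n // 2),
            "sire": assinica["sire"], "dam": assinica["dam"], "mature": False,
        })
        res = strain_comparison(df, "y")
        assert res["comparisons"]["diff"].abs().max() == pytest.approx(0.0, abs=1e-10)
        assert (res["comparisons"]["p_tukey"] == 1.0).all()

    def test_shifted_strain_detected(self, two_strains):
        df = two_strains.copy()
        df.loc[df.strain == "B", "y"] += 3.0
        res = strain_comparison(df, "y")
        assert (res["comparisons"]["p_tukey"] < 0.001).all()
        ls = res["lsmeans"].set_index("strain")["lsmean"]
        assert ls["B"] - ls["A"] == pytest.approx(3.0, abs=0.5)

    def test_single_strain_rejected(self, two_strains):
        df = two_strains.assign(strain="A")
        with pytest.raises(ValueError, match="two strains"):
            strain_comparison(df, "y")

    def test_single_family_strain_warns(self, assinica):
        n = assinica["n"]
        strain = np.where(assinica["family"] == assinica["family"][0], "Solo", "Rest")
        df = pd.DataFrame({"y": np.random.default_rng(12).normal(size=n),
                           "strain": strain, "sire": assinica["sire"],
                           "dam": assinica["dam"], "mature": False})
        with pytest.warns(UserWarning, match="single family"):
            res = strain_comparison(df, "y")
        assert len(res["comparisons"]) == 1
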