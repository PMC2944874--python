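"""REML animal-model variance components, heritability, and related tests.

The animal model is the mixed model y = Xb + Z a + (M c) + (F f) + e where
the additive genetic effects a have covariance A * V_a (A the numerator
relationship matrix from the pedigree), dam effects c are iid with variance
V_m, full-sib family effects f iid with variance V_c, and e iid residual.
Variance components are estimated by restricted maximum likelihood on the
log-variance scale with a bound-constrained quasi-Newton optimizer and
multiple restarts.  Heritability is h^2 = V_a / (V_a + V_m + V_c + V_e) and
the dam-effect ratio m^2 = V_m / V_p; their standard errors come from a
delta-method expansion around the numerical information matrix.

Significance of a variance component is assessed with a likelihood-ratio
test: twice the log-likelihood difference between the full model and the
model without that component, referred to a chi-square distribution with one
degree of freedom.  Because the null value lies on the boundary of the
parameter space this reference is conservative; the exact 50:50 mixture of a
point mass at zero and chi-square(1) is available via
``boundary_correction=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .pedigree import RelationshipMatrix

__all__ = [
    "AnimalModelREML",
    "LRTResult",
    "GeneticCorrelation",
    "reml_fit",
    "reml_loglik",
    "lrt_component",
    "genetic_correlation",
    "strain_comparison",
]

_LOG_LO, _LOG_HI = -12.0, 6.0  # bounds on log(sigma^2 / var(y))


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


@dataclass
class GeneticCorrelation:
    cov_a: float
    r_g: float
    se: float
    components: dict
    loglik: float
    lrt: LRTResult


def _groups_to_cov(labels) -> np.ndarray:
    """Z Z' for an iid random effect grouped by ``labels``."""
    labels = np.asarray(labels)
    codes, _ = pd.factorize(labels)
    Z = np.eye(codes.max() + 1)[codes]
    return Z @ Z.T


def reml_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ N(Xb, V) with b profiled out.

    Uses the orthonormal-error-contrast convention:
    -0.5 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| - log|X'X| + y'Py ].
    """
    n, p = X.shape
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = cho_solve((c, low), X)
    Viy = cho_solve((c, low), y)
    XtViX = X.T @ ViX
    cx = np.linalg.cholesky(XtViX)
    logdetXtViX = 2.0 * np.sum(np.log(np.diag(cx)))
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    yPy = float(y @ Viy - (X.T @ Viy) @ beta)
    sign, logdetXtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetXtViX - logdetXtX + yPy)


def _gls_beta(y, X, V):
    c, low = cho_factor(V, lower=True)
    ViX = cho_solve((c, low), X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    return beta, np.linalg.inv(XtViX)


class _VarianceObjective:
    """Negative REML loglik over log-variances, with covariance parts cached."""

    def __init__(self, y, X, covs):
        self.y = y
        self.X = X
        self.covs = covs  # list of n x n covariance structures, residual last is I
        self.n = y.size

    def build_V(self, theta):
        V = np.zeros((self.n, self.n))
        for t, M in zip(theta, self.covs):
            V += np.exp(t) * M
        return V

    def __call__(self, theta):
        try:
            return -reml_loglik(self.y, self.X, self.build_V(theta))
        except np.linalg.LinAlgError:
            return 1e12


def _check_full_rank(X: np.ndarray, names=None):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name an aliased column for the error message
        q, rr = np.linalg.qr(X)
        bad = [j for j in range(X.shape[1]) if abs(rr[j, j]) < 1e-8 * abs(rr).max()]
        lab = [names[j] for j in bad] if names else bad
        raise ValueError(f"fixed-effect design is singular; aliased columns: {lab}")


class AnimalModelREML(BaseEstimator):
    """Animal-model REML estimator in sklearn style.

    Parameters
    ----------
    random_terms : tuple of {"additive", "dam", "family", "sire"}
        Which random effects to fit besides the residual.
    n_restarts : int
        Optimizer restarts from spread starting variance shares.
    compute_se : bool
        Whether to compute delta-method standard errors for h2 and m2.
    boundary_correction : bool
        Use the 50:50 boundary mixture for LRT p-values produced by
        :func:`lrt_component` on this fit (stored on the fit; the default
        chi-square(1) reference matches common reporting practice).

    ``fit(X, y, relationship=..., dam=..., family=..., sire=...)`` takes the
    fixed-effect design matrix ``X`` (or ``None`` for an intercept only), the
    trait vector ``y``, the relationship matrix aligned with ``y`` (required
    for the "additive" term), and grouping-label arrays for the iid terms.

    Attributes
    ----------
    varcomp_ : dict of fitted variance components (includes "residual").
    vp_ : total phenotypic variance.
    h2_, h2_se_ : heritability and its standard error.
    m2_, m2_se_ : dam-effect ratio (present when "dam" is fitted).
    loglik_ : maximized restricted log-likelihood.
    beta_ : GLS fixed-effect solutions at the REML estimates.
    converged_ : optimizer success flag.
    """

    def __init__(self, random_terms=("additive",), n_restarts=3, tol=1e-8,
                 compute_se=True, boundary_correction=False):
        self.random_terms = random_terms
        self.n_restarts = n_restarts
        self.tol = tol
        self.compute_se = compute_se
        self.boundary_correction = boundary_correction

    # ------------------------------------------------------------------
    def _covariances(self, n, relationship, dam, family, sire):
        covs, names = [], []
        for term in self.random_terms:
            if term == "additive":
                if relationship is None:
                    raise ValueError("'additive' term needs a relationship matrix")
                A = relationship.values if isinstance(relationship, RelationshipMatrix) else np.asarray(relationship)
                if A.shape != (n, n):
                    raise ValueError("relationship matrix does not match y")
                covs.append(A)
            elif term == "dam":
                if dam is None:
                    raise ValueError("'dam' term needs dam labels")
                covs.append(_groups_to_cov(dam))
            elif term == "family":
                if family is None:
                    raise ValueError("'family' term needs family labels")
                if dam is not None:
                    fam_of_dam = pd.Series(np.asarray(family)).groupby(np.asarray(dam)).nunique()
                    if (fam_of_dam == 1).all():
                        raise ValueError(
                            "family effects are completely confounded with the sire-dam "
                            "structure (no dam appears in more than one family: egg lots "
                            "were not split); drop the 'family' term"
                        )
                covs.append(_groups_to_cov(family))
            elif term == "sire":
                if sire is None:
                    raise ValueError("'sire' term needs sire labels")
                covs.append(_groups_to_cov(sire))
            else:
                raise ValueError(f"unknown random term {term!r}")
            names.append(term)
        covs.append(np.eye(n))
        names.append("residual")
        return covs, names

    def fit(self, X, y, *, relationship=None, dam=None, family=None, sire=None,
            feature_names=None):
        y = np.asarray(y, float).ravel()
        n = y.size
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if n < X.shape[1] + 2:
            raise ValueError("too few observations for the fixed-effect design")
        _check_full_rank(X, feature_names)

        covs, names = self._covariances(n, relationship, dam, family, sire)
        # the restricted likelihood depends on y only through Py, so the OLS
        # residuals can stand in for y; this makes fits exactly invariant to
        # translations (and well-conditioned for traits with large means)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        vy = float(np.var(resid))
        if vy <= 0:
            raise ValueError("trait has zero variance")
        ys = resid / np.sqrt(vy)
        obj = _VarianceObjective(ys, X, covs)

        k = len(covs)
        starts = []
        for share in (0.3, 0.6, 0.05)[: max(1, self.n_restarts)]:
            v = np.full(k, share / (k - 1)) if k > 1 else np.array([1.0])
            v[-1] = 1.0 - share
            starts.append(np.log(np.clip(v, 1e-5, None)))
        best = None
        bounds = [(_LOG_LO, _LOG_HI)] * k
        for s in starts:
            res = optimize.minimize(obj, s, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        comps = np.exp(theta) * vy
        comps[np.exp(theta) < 2e-5] = 0.0  # at lower bound -> exact zero
        self.varcomp_ = dict(zip(names, comps))
        self.vp_ = float(comps.sum())
        self.loglik_ = float(-best.fun - 0.5 * (n - X.shape[1]) * np.log(vy))
        self.converged_ = bool(best.success)
        self.h2_ = float(self.varcomp_.get("additive", 0.0) / self.vp_)
        self.m2_ = float(self.varcomp_.get("dam", 0.0) / self.vp_) if "dam" in names else None
        self.c2_ = float(self.varcomp_.get("family", 0.0) / self.vp_) if "family" in names else None

        V = obj.build_V(theta) * vy
        self.beta_, self.beta_cov_ = _gls_beta(y, X, V)
        self._names = names
        self._theta = theta
        self._obj = obj
        self._vy = vy
        self.n_ = n

        self.h2_se_ = self.m2_se_ = None
        if self.compute_se:
            self._delta_se(theta, names)
        return self

    # ------------------------------------------------------------------
    def _delta_se(self, theta, names, step=1e-4):
        """Delta-method SEs of h2 (and m2) from a central-difference Hessian
        of the REML loglik on the log-variance scale."""
        k = theta.size
        H = np.zeros((k, k))
        f0 = self._obj(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = step
                ej = np.zeros(k); ej[j] = step
                fpp = self._obj(theta + ei + ej)
                fpm = self._obj(theta + ei - ej)
                fmp = self._obj(theta - ei + ej)
                fmm = self._obj(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
        # H is the Hessian of -loglik; its inverse approximates cov(theta)
        try:
            cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            return
        sig = np.exp(theta)  # on the scaled-variance scale; ratios are scale-free
        vp = sig.sum()

        def ratio_grad(idx):
            g = np.empty(k)
            for i in range(k):
                d = (vp - sig[idx]) / vp**2 if i == idx else -sig[idx] / vp**2
                g[i] = sig[i] * d  # chain rule through theta = log sigma^2
            return g

        if "additive" in names:
            g = ratio_grad(names.index("additive"))
            v = float(g @ cov @ g)
            self.h2_se_ = float(np.sqrt(v)) if v > 0 else np.nan
        if "dam" in names:
            g = ratio_grad(names.index("dam"))
            v = float(g @ cov @ g)
            self.m2_se_ = float(np.sqrt(v)) if v > 0 else np.nan


def reml_fit(y, X=None, *, relationship=None, dam=None, family=None, sire=None,
             random_terms=("additive",), feature_names=None, **kwargs) -> AnimalModelREML:
    """Functional wrapper: fit an animal model and return the fitted estimator."""
    est = AnimalModelREML(random_terms=random_terms, **kwargs)
    return est.fit(X, y, relationship=relationship, dam=dam, family=family, sire=sire,
                   feature_names=feature_names)


def lrt_component(full: AnimalModelREML, reduced: AnimalModelREML,
                  boundary_correction: bool | None = None) -> LRTResult:
    """Likelihood-ratio test of the one random term dropped from ``full``."""
    ft, rt = set(full.random_terms), set(reduced.random_terms)
    if not (rt < ft and len(ft - rt) == 1):
        raise ValueError("reduced model must drop exactly one random term of the full model")
    stat = max(0.0, 2.0 * (full.loglik_ - reduced.loglik_))
    if boundary_correction is None:
        boundary_correction = full.boundary_correction
    if boundary_correction:
        p = 0.5 * stats.chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = float(stats.chi2.sf(stat, 1))
    return LRTResult(float(stat), 1, float(p))


# ---------------------------------------------------------------------------
# bivariate animal model

def _bivariate_V(A, n, G, R):
    V = np.empty((2 * n, 2 * n))
    I = np.eye(n)
    V[:n, :n] = G[0, 0] * A + R[0, 0] * I
    V[n:, n:] = G[1, 1] * A + R[1, 1] * I
    V[:n, n:] = V[n:, :n] = G[0, 1] * A + R[0, 1] * I
    return V


def _chol_from_params(p3):
    l11, l21, l22 = np.exp(p3[0]), p3[1], np.exp(p3[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def genetic_correlation(y1, y2, X=None, *, relationship, n_restarts=2,
                        constrain_zero=False, compute_se=True) -> GeneticCorrelation:
    """Bivariate REML genetic correlation between two traits on the same fish.

    The 2x2 additive (G) and residual (R) covariance matrices are each
    parameterized by their Cholesky factors, which keeps every proposal
    positive semidefinite.  The LRT compares the full fit against the fit
    with the additive covariance pinned to zero (chi-square, 1 df).
    """
    y1 = np.asarray(y1, float).ravel()
    y2 = np.asarray(y2, float).ravel()
    n = y1.size
    if y2.size != n:
        raise ValueError("traits must be measured on the same individuals")
    A = relationship.values if isinstance(relationship, RelationshipMatrix) else np.asarray(relationship)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, float)
    Xb = np.kron(np.eye(2), X)
    s1, s2 = np.std(y1), np.std(y2)
    yb = np.concatenate([y1 / s1, y2 / s2])

    def fit_once(free_cov):
        def nll(p):
            if free_cov:
                G = _chol_from_params(p[0:3])
                R = _chol_from_params(p[3:6])
            else:
                G = np.diag(np.exp(p[0:2]))
                R = _chol_from_params(p[2:5])
            try:
                return -reml_loglik(yb, Xb, _bivariate_V(A, n, G, R))
            except np.linalg.LinAlgError:
                return 1e12
        k = 6 if free_cov else 5
        best = None
        for h2 in (0.3, 0.6)[:max(1, n_restarts)]:
            if free_cov:
                p0 = np.array([np.log(np.sqrt(h2)), 0.0, np.log(np.sqrt(h2)),
                               np.log(np.sqrt(1 - h2)), 0.0, np.log(np.sqrt(1 - h2))])
            else:
                p0 = np.array([np.log(h2), np.log(h2),
                               np.log(np.sqrt(1 - h2)), 0.0, np.log(np.sqrt(1 - h2))])
            res = optimize.minimize(nll, p0, method="L-BFGS-B",
                                    bounds=[(-8, 4)] * k,
                                    options={"ftol": 1e-12, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        return best, nll

    full, nll_full = fit_once(True)
    G = _chol_from_params(full.x[0:3])
    R = _chol_from_params(full.x[3:6])
    # rescale back to trait units
    S = np.diag([s1, s2])
    Gu, Ru = S @ G @ S, S @ R @ S
    r_g = float(Gu[0, 1] / np.sqrt(Gu[0, 0] * Gu[1, 1])) if Gu[0, 0] > 0 and Gu[1, 1] > 0 else np.nan
    ll_full = float(-full.fun)

    red, _ = fit_once(False)
    stat = max(0.0, 2.0 * ((-full.fun) - (-red.fun)))
    lrt = LRTResult(float(stat), 1, float(stats.chi2.sf(stat, 1)))

    se = np.nan
    if compute_se:
        step = 1e-4
        p = full.x.copy()

        def rg_of(pv):
            Gp = _chol_from_params(pv[0:3])
            return Gp[0, 1] / np.sqrt(Gp[0, 0] * Gp[1, 1])

        k = p.size
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = step
                ej = np.zeros(k); ej[j] = step
                H[i, j] = H[j, i] = (nll_full(p + ei + ej) - nll_full(p + ei - ej)
                                     - nll_full(p - ei + ej) + nll_full(p - ei - ej)) / (4 * step * step)
        cov = np.linalg.pinv(H)
        g = optimize.approx_fprime(p, rg_of, 1e-6)
        v = float(g @ cov @ g)
        se = float(np.sqrt(v)) if v > 0 else np.nan

    comps = {"V_a1": Gu[0, 0], "V_a2": Gu[1, 1], "cov_a": Gu[0, 1],
             "V_e1": Ru[0, 0], "V_e2": Ru[1, 1], "cov_e": Ru[0, 1]}
    return GeneticCorrelation(float(Gu[0, 1]), r_g, se, comps, ll_full, lrt)


# ---------------------------------------------------------------------------
# strain comparison mixed model

def strain_comparison(df: pd.DataFrame, trait: str, *, strain_col="strain",
                      mature_col="mature", sire_col="sire", dam_col="dam",
                      n_restarts=2) -> dict:
    """Mixed model with strain (+ maturation) fixed and sire + dam random.

    Returns a dict with the variance components, the least-squares strain
    means (maturation balanced at 0.5 when it varies), and Tukey-Kramer
    adjusted pairwise comparisons based on the studentized range with
    between-family degrees of freedom.
    """
    strains = sorted(df[strain_col].unique())
    if len(strains) < 2:
        raise ValueError("need at least two strains")
    fam = df[sire_col].astype(str) + "x" + df[dam_col].astype(str)
    for s in strains:
        if fam[df[strain_col] == s].nunique() < 2:
            warnings.warn(f"strain {s!r} has a single family; comparison retained",
                          stacklevel=2)
    y = df[trait].to_numpy(float)
    n = y.size
    if np.var(y) == 0:
        # degenerate but well-defined: every LS-mean equals the constant
        lsmeans = pd.DataFrame({"strain": strains, "lsmean": y[0], "se": 0.0})
        rows = [{"strain_a": a, "strain_b": b, "diff": 0.0, "se": 0.0, "p_tukey": 1.0}
                for i, a in enumerate(strains) for b in strains[i + 1:]]
        return {"varcomp": {"sire": 0.0, "dam": 0.0, "residual": 0.0},
                "lsmeans": lsmeans, "comparisons": pd.DataFrame(rows), "fit": None}
    cols = [np.ones(n)]
    names = ["intercept"]
    for s in strains[1:]:
        cols.append((df[strain_col] == s).to_numpy(float))
        names.append(f"strain[{s}]")
    use_mature = mature_col in df and df[mature_col].nunique() > 1
    if use_mature:
        cols.append(df[mature_col].to_numpy(float))
        names.append("mature")
    X = np.column_stack(cols)

    est = AnimalModelREML(random_terms=("sire", "dam"), n_restarts=n_restarts,
                          compute_se=False)
    est.fit(X, y, sire=df[sire_col].to_numpy(), dam=df[dam_col].to_numpy(),
            feature_names=names)

    # LS-means: strain dummies at 0/1, maturation balanced
    lvec = {}
    for s in strains:
        v = np.zeros(X.shape[1])
        v[0] = 1.0
        if s in strains[1:]:
            v[1 + strains.index(s) - 1] = 1.0
        if use_mature:
            v[-1] = 0.5
        lvec[s] = v
    C = est.beta_cov_
    lsmeans = pd.DataFrame({
        "strain": strains,
        "lsmean": [float(lvec[s] @ est.beta_) for s in strains],
        "se": [float(np.sqrt(lvec[s] @ C @ lvec[s])) for s in strains],
    })
    k = len(strains)
    ddf = max(int(fam.nunique() - k), 2)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = lvec[strains[i]] - lvec[strains[j]]
            diff = float(d @ est.beta_)
            se = float(np.sqrt(d @ C @ d))
            q = abs(diff) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, ddf)) if np.isfinite(q) else 0.0
            if se == 0 and diff == 0:
                p = 1.0
            rows.append({"strain_a": strains[i], "strain_b": strains[j],
                         "diff": diff, "se": se, "p_tukey": min(p, 1.0)})
    return {"varcomp": est.varcomp_, "lsmeans": lsmeans,
            "comparisons": pd.DataFrame(rows), "fit": est}
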