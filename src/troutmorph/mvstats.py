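"""Strain-level multivariate comparisons of warp scores.

Wilks' lambda MANOVA, the MANCOVA homogeneity-of-slopes (strain x size
interaction) test, leave-one-out linear discriminant reclassification on
equal per-family subsamples, and split-plot repeated-measures ANOVA on
family-mean warp scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

logger = logging.getLogger(__name__)

__all__ = [
    "WilksResult",
    "manova_wilks",
    "mancova_interaction",
    "dfa_loo",
    "repeated_measures_family_means",
]


@dataclass
class WilksResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float


def _rao_F(lam: float, p: int, q: int, ve: float) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda with p variables and q
    hypothesis df on ve error df."""
    if p * q == 2 or min(p, q) == 1:
        t = 1.0
    else:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    df1 = p * q
    df2 = t * (ve - (p - q + 1) / 2.0) - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t <= 0:
        return np.inf, df1, df2, 0.0
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    return float(F), float(df1), float(df2), pval


def _truncate_if_singular(Y: np.ndarray, W: np.ndarray) -> np.ndarray | None:
    """Return leading-PC projection of Y if the within scatter is singular."""
    rank = np.linalg.matrix_rank(W)
    if rank == W.shape[0]:
        return None
    logger.info("within-group scatter singular; truncating to %d leading axes", rank)
    Yc = Y - Y.mean(axis=0)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    return Y @ vt[:rank].T


def manova_wilks(scores, groups) -> WilksResult:
    """One-way MANOVA: Wilks' lambda = |W| / |W + B| with Rao's F."""
    Y = np.asarray(scores, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    n, p = Y.shape
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in labels:
        sub = Y[groups == g]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        m = sub.mean(axis=0)
        d = sub - m
        W += d.T @ d
        B += sub.shape[0] * np.outer(m - grand, m - grand)
    trunc = _truncate_if_singular(Y, W)
    if trunc is not None:
        return manova_wilks(trunc, groups)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    q = len(labels) - 1
    ve = n - len(labels)
    F, df1, df2, pval = _rao_F(lam, p, q, ve)
    return WilksResult(lam, F, df1, df2, pval)


def _mlm_residual_scatter(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual SSCP of the multivariate linear model Y = X B + E."""
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ B
    return R.T @ R, int(np.linalg.matrix_rank(X))


def mancova_interaction(scores, groups, covariate) -> WilksResult:
    """Homogeneity-of-slopes test: Wilks' lambda for the group x covariate
    interaction in a multivariate linear model (differences in allometry)."""
    Y = np.asarray(scores, float)
    groups = np.asarray(groups)
    x = np.asarray(covariate, float).ravel()
    labels = pd.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("interaction undefined with a single group")
    for lab in labels:
        if np.ptp(x[groups == lab]) <= 0:
            raise ValueError(f"covariate constant within group {lab!r}")
    n, p = Y.shape
    D = np.column_stack([(groups == lab).astype(float) for lab in labels])
    X_common = np.column_stack([D, x])                      # separate means, common slope
    X_full = np.column_stack([D, D * x[:, None]])           # separate slopes
    E_full, rank_full = _mlm_residual_scatter(Y, X_full)
    trunc = _truncate_if_singular(Y, E_full)
    if trunc is not None:
        return mancova_interaction(trunc, groups, covariate)
    E_common, _ = _mlm_residual_scatter(Y, X_common)
    H = E_common - E_full
    lam = float(np.linalg.det(E_full) / np.linalg.det(E_full + H))
    q = g - 1                   # extra slope df
    ve = n - rank_full
    F, df1, df2, pval = _rao_F(lam, p, q, ve)
    return WilksResult(lam, F, df1, df2, pval)


def dfa_loo(scores, groups, families=None, per_family_subsample: int | None = None,
            seed: int | None = None) -> pd.DataFrame:
    """Leave-one-out linear discriminant reclassification percentages.

    When ``families`` and ``per_family_subsample`` are given, an equal-count
    random subsample (seeded) is drawn from each family first.  The
    discriminant uses a pooled covariance and equal priors; each observation
    is classified by a rule refit without it.  Rows of the returned matrix
    (true group x assigned group, in percent) sum to 100.
    """
    Y = np.asarray(scores, float)
    groups = np.asarray(groups)
    if per_family_subsample is not None:
        if families is None:
            raise ValueError("per-family subsampling needs family labels")
        if seed is None:
            raise ValueError("a seed is required for per-family subsampling")
        rng = np.random.default_rng(seed)
        fam = np.asarray(families)
        keep = []
        for f in pd.unique(fam):
            idx = np.flatnonzero(fam == f)
            if idx.size < per_family_subsample:
                raise ValueError(f"family {f!r} smaller than the subsample size")
            keep.extend(rng.choice(idx, size=per_family_subsample, replace=False))
        keep = np.sort(np.asarray(keep))
        logger.info("DFA subsample: %d of %d observations (seed=%s)", keep.size, Y.shape[0], seed)
        Y, groups = Y[keep], groups[keep]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    # guard singular pooled covariance by truncating to leading axes
    W = np.zeros((Y.shape[1], Y.shape[1]))
    for g in labels:
        d = Y[groups == g] - Y[groups == g].mean(axis=0)
        W += d.T @ d
    trunc = _truncate_if_singular(Y, W)
    if trunc is not None:
        Y = trunc
    n = Y.shape[0]
    priors = np.full(len(labels), 1.0 / len(labels))
    assigned = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(priors=priors)
        lda.fit(Y[mask], groups[mask])
        assigned[i] = lda.predict(Y[i:i + 1])[0]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for g in labels:
        sub = assigned[groups == g]
        for h in labels:
            mat.loc[g, h] = 100.0 * np.mean(sub == h)
    return mat


def repeated_measures_family_means(scores: pd.DataFrame, value_col: str,
                                   family_col="family", strain_col="strain",
                                   period_col="period") -> pd.DataFrame:
    """Split-plot repeated-measures ANOVA on family-mean scores.

    Families are the whole plots (strain the between-family factor), sampling
    period the within-family factor.  Strain is tested against the
    family-within-strain mean square; period and strain x period against the
    residual.  Families observed in fewer than two periods are dropped.
    """
    import warnings

    df = scores.groupby([family_col, strain_col, period_col], as_index=False)[value_col].mean()
    counts = df.groupby(family_col)[period_col].nunique()
    bad = counts[counts < 2].index
    if len(bad):
        warnings.warn(f"dropping families with one period: {list(bad)}", stacklevel=2)
        df = df[~df[family_col].isin(bad)]
    if df[family_col].nunique() < 2:
        raise ValueError("repeated-measures analysis needs at least two families")
    if df[strain_col].nunique() < 2:
        raise ValueError("need at least two strains")
    y = df[value_col].to_numpy(float)
    n = y.size

    def dummies(col):
        return pd.get_dummies(df[col].astype(str)).to_numpy(float)

    strain_d = dummies(strain_col)
    fam_d = dummies(family_col)
    period_d = dummies(period_col)
    inter_d = np.concatenate(
        [strain_d * period_d[:, j:j + 1] for j in range(period_d.shape[1])], axis=1)

    # Sequential (type I) sums of squares via nested projections; this keeps
    # the degrees of freedom right even though family is nested in strain.
    blocks = [np.ones((n, 1)), strain_d, fam_d, period_d, inter_d]
    fitted_ss, ranks = [], []
    Xacc = np.empty((n, 0))
    for b in blocks:
        Xacc = np.column_stack([Xacc, b])
        beta, *_ = np.linalg.lstsq(Xacc, y, rcond=None)
        fitted_ss.append(float(((Xacc @ beta) ** 2).sum()))
        ranks.append(int(np.linalg.matrix_rank(Xacc)))
    ss = np.diff(fitted_ss)
    dfs = np.diff(ranks)
    ss_res = float((y ** 2).sum() - fitted_ss[-1])
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom (need replication across periods)")
    names = ["strain", "family", "period", "strain:period"]
    ms = {nm: (s / d if d > 0 else np.nan) for nm, s, d in zip(names, ss, dfs)}
    dfd = dict(zip(names, dfs))
    ms_res = ss_res / df_res
    if dfd["family"] < 1:
        raise ValueError("no between-family degrees of freedom")
    rows = []
    F = ms["strain"] / ms["family"]
    rows.append(("strain", F, dfd["strain"], dfd["family"],
                 stats.f.sf(F, dfd["strain"], dfd["family"])))
    F = ms["period"] / ms_res
    rows.append(("period", F, dfd["period"], df_res,
                 stats.f.sf(F, dfd["period"], df_res)))
    F = ms["strain:period"] / ms_res
    rows.append(("strain:period", F, dfd["strain:period"], df_res,
                 stats.f.sf(F, dfd["strain:period"], df_res)))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
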