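"""Landmark-based geometric morphometrics.

Raw digitized configurations (k landmarks in 2-D) are turned into shape
variables in three steps:

1. generalized Procrustes analysis (GPA): translation, scale and rotation are
   removed by iterative superimposition onto a consensus shape;
2. the thin-plate-spline bending-energy matrix of the consensus defines
   principal warps; projecting each specimen's deviation from the consensus
   onto them (plus the two uniform/affine components) gives partial-warp
   scores, a full orthonormal basis of the 2k-4 dimensional shape tangent
   space;
3. a singular value decomposition of the partial-warp score matrix gives
   relative warps — principal components of shape, ordered by variance.

The whole chain is exposed as the sklearn-style :class:`RelativeWarps`
estimator; the module-level functions are thin wrappers kept for scripting.

Centroid size is implemented as the root summed squared deviation of the
landmarks from their centroid.  (The equivalent "root summed squared
inter-landmark distances" definition differs only by the constant factor
sqrt(k) at fixed k, and so changes no shape variable.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "ProcrustesResult",
    "WarpBasis",
    "WarpScores",
    "read_tps",
    "write_tps",
    "centroid_size",
    "gpa",
    "warp_basis",
    "warp_scores",
    "RelativeWarps",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks (k x 2), with optional physical scale."""

    id: str
    points: np.ndarray
    scale: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be k x 2")
        if self.points.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinate")


@dataclass
class ProcrustesResult:
    consensus: np.ndarray        # k x 2
    aligned: np.ndarray          # n x k x 2
    centroid_sizes: np.ndarray   # n
    ids: list[str]
    iterations: int
    converged: bool


@dataclass
class WarpBasis:
    bending_energy: np.ndarray    # k x k
    principal_warps: np.ndarray   # k x (k-3), columns orthonormal
    eigenvalues: np.ndarray       # k-3 positive bending energies
    uniform_basis: np.ndarray     # 2k x 2, columns orthonormal in tangent space
    consensus: np.ndarray
    alpha: float = 0.0


@dataclass
class WarpScores:
    partial: np.ndarray           # n x (2k-4)
    relative: np.ndarray          # n x (2k-4)
    variance_fraction: np.ndarray
    loadings: np.ndarray          # (2k-4) x (2k-4), partial-warp -> relative-warp
    ids: list[str]

    @property
    def n_axes(self) -> int:
        """Number of relative-warp axes carrying variance."""
        total = self.variance_fraction.sum()
        return int(np.sum(self.variance_fraction > 1e-12 * max(total, 1.0)))


# ---------------------------------------------------------------------------
# TPS landmark file format

def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file (LM=, coordinate lines, ID=, IMAGE=, SCALE=).

    SCALE is applied multiplicatively to the stored coordinates.
    """
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i, rec = 0, 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        if not lines[i].upper().startswith("LM="):
            raise ValueError(f"record {rec}: expected LM=, got {lines[i]!r}")
        k = int(lines[i].split("=", 1)[1])
        i += 1
        pts = []
        while len(pts) < k and i < len(lines):
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(f"record {rec}: expected {k} coordinate lines, "
                                 f"got {len(pts)} before {lines[i]!r}")
            pts.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(pts) != k:
            raise ValueError(f"record {rec}: LM={k} but only {len(pts)} coordinate lines")
        cid, scale = f"specimen_{rec}", None
        while i < len(lines) and lines[i] and not lines[i].upper().startswith("LM="):
            key, _, val = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                cid = val.strip()
            elif key == "SCALE":
                scale = float(val)
            i += 1
        pts = np.asarray(pts)
        if scale is not None:
            pts = pts * scale
        configs.append(LandmarkConfiguration(cid, pts, scale))
        rec += 1
    if not configs:
        logger.warning("empty TPS file: %s", path)
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations in TPS format; coordinates at full precision.

    Stored coordinates are divided by SCALE when one is present so that a
    read/write round trip is exact.
    """
    with open(path, "w") as fh:
        for c in configs:
            pts = c.points if c.scale is None else c.points / c.scale
            fh.write(f"LM={pts.shape[0]}\n")
            for x, y in pts:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={c.id}\n")
            if c.scale is not None:
                fh.write(f"SCALE={float(c.scale)!r}\n")


# ---------------------------------------------------------------------------
# size and superimposition

def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered ** 2).sum()))
    if cs < 1e-12:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _rotate_onto(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Best proper rotation (det=+1) of centered x onto centered target."""
    u, _, vt = np.linalg.svd(target.T @ x)
    r = (u @ vt).T
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = (u @ vt).T
    return x @ r


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation bringing a shape to a deterministic orientation.

    The GPA fixed point is unique only up to a joint rotation of consensus
    and aligned specimens; rotating to the consensus' principal axes (major
    axis on x, 180-degree ambiguity resolved by the sign of the third moment,
    falling back to the first landmark) makes the output orientation — and
    hence every downstream warp score — independent of how the input
    configurations happened to be oriented.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    R = vecs[:, ::-1]  # major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] *= -1
    rot = consensus @ R
    for moment in (rot[:, 0] ** 3, rot[:, 1] ** 3, [rot[0, 0]], [rot[0, 1]]):
        s = float(np.sum(moment))
        if abs(s) > 1e-9:
            if s < 0:
                R = -R  # 180-degree turn keeps det = +1 in 2-D
            break
    return R


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    ids: list[str] | None = None,
) -> ProcrustesResult:
    """Iterative generalized Procrustes superimposition (partial Procrustes).

    Each configuration is centered, scaled to unit centroid size, and rotated
    onto the running consensus; the consensus is the mean of the aligned
    configurations, renormalized to unit centroid size.  Iteration stops when
    the consensus moves less than ``tol`` (root-mean-square displacement).
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        ids = ids or [f"specimen_{i}" for i in range(arr.shape[0])]
    else:
        arr = np.stack([c.points for c in configs])
        ids = ids or [c.id for c in configs]
    n, k, _ = arr.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    sizes = np.empty(n)
    aligned = np.empty_like(arr)
    for i in range(n):
        centered = arr[i] - arr[i].mean(axis=0)
        sizes[i] = centroid_size(centered)
        aligned[i] = centered / sizes[i]

    consensus = aligned[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = _rotate_onto(aligned[i], consensus)
        new = aligned.mean(axis=0)
        new = new - new.mean(axis=0)
        new = new / centroid_size(new)
        shift = np.sqrt(((new - consensus) ** 2).mean())
        consensus = new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)
    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    for i in range(n):
        aligned[i] = _rotate_onto(aligned[i] @ R, consensus)
    return ProcrustesResult(consensus, aligned, sizes, list(ids), it, converged)


# ---------------------------------------------------------------------------
# thin-plate-spline warps

def _tps_kernel(consensus: np.ndarray) -> np.ndarray:
    d2 = ((consensus[:, None, :] - consensus[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    return K


def warp_basis(consensus: np.ndarray, alpha: float = 0.0) -> WarpBasis:
    """Bending-energy matrix, principal warps and uniform basis at a consensus.

    The bending-energy matrix is the upper-left k x k block of the inverse of
    the TPS system [[K, Q], [Q', 0]] with kernel U(r) = r^2 log r^2 and
    Q = [1 | x | y].  Its k-3 positive-eigenvalue eigenvectors are the
    principal warps; the 2-D uniform (affine) shape basis is the orthogonal
    complement of the non-uniform subspace within the shape tangent space.
    """
    X = np.asarray(consensus, float)
    k = X.shape[0]
    K = _tps_kernel(X)
    Q = np.column_stack([np.ones(k), X])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (collinear landmarks?)") from exc
    Be = Linv[:k, :k]
    Be = 0.5 * (Be + Be.T)
    evals, evecs = np.linalg.eigh(Be)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    nz = evals > 1e-10 * max(evals.max(), 1.0)
    if nz.sum() != k - 3:
        raise ValueError(f"expected {k - 3} positive bending energies, got {int(nz.sum())}")
    pw = evecs[:, nz]        # k x (k-3), orthonormal, orthogonal to span{1, x, y}
    lam = evals[nz]

    # Tangent space at the consensus: R^{2k} minus translations (2), rotation
    # (1) and scale (1) -> 2k-4 dims.  Non-uniform part: pw applied to x and y
    # coordinates (2k-6 dims).  The uniform basis spans what is left.
    c = X.ravel()
    c = c / np.linalg.norm(c)
    rot = np.column_stack([X[:, 1], -X[:, 0]]).ravel()
    rot = rot / np.linalg.norm(rot)
    tx = np.zeros(2 * k)
    tx[0::2] = 1
    ty = np.zeros(2 * k)
    ty[1::2] = 1
    nonshape = np.column_stack([tx / np.sqrt(k), ty / np.sqrt(k), c, rot])
    nonuni = np.zeros((2 * k, k - 3, 2))
    nonuni[0::2, :, 0] = pw
    nonuni[1::2, :, 1] = pw
    nonuni = nonuni.reshape(2 * k, -1)
    # orthonormal complement of [nonshape | nonuniform] is the uniform subspace
    Mfull = np.column_stack([nonshape, nonuni])
    q, _ = np.linalg.qr(Mfull, mode="complete")
    uniform = q[:, Mfull.shape[1]:]
    if uniform.shape[1] != 2:
        raise ValueError("uniform subspace is not 2-dimensional")
    return WarpBasis(Be, pw, lam, uniform, X.copy(), alpha)


def warp_scores(proc: ProcrustesResult, basis: WarpBasis) -> WarpScores:
    """Partial- and relative-warp scores for GPA-aligned specimens.

    Partial scores stack, per principal warp, the x- and y-projections of the
    deviation from the consensus (weighted by eigenvalue^(-alpha/2) when
    alpha != 0), followed by the two uniform scores.  Relative warps are the
    principal components (SVD about the column mean) of this score matrix,
    each axis oriented so its largest-magnitude loading is positive.
    """
    n, k, _ = proc.aligned.shape
    dev = proc.aligned - basis.consensus[None]         # n x k x 2
    w = basis.eigenvalues ** (-basis.alpha / 2.0) if basis.alpha else np.ones_like(basis.eigenvalues)
    px = dev[:, :, 0] @ basis.principal_warps * w      # n x (k-3)
    py = dev[:, :, 1] @ basis.principal_warps * w
    nonuni = np.empty((n, 2 * (k - 3)))
    nonuni[:, 0::2] = px
    nonuni[:, 1::2] = py
    uni = dev.reshape(n, 2 * k) @ basis.uniform_basis  # n x 2
    partial = np.column_stack([nonuni, uni])

    if n <= partial.shape[1]:
        warnings.warn(
            f"n={n} specimens span at most {n - 1} of {partial.shape[1]} axes; "
            "trailing relative warps have zero variance", stacklevel=2)
    centered = partial - partial.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    p = partial.shape[1]
    if s.size < p:  # pad degenerate case
        s = np.concatenate([s, np.zeros(p - s.size)])
        vt = np.vstack([vt, np.zeros((p - vt.shape[0], p))])
    rel = centered @ vt.T
    # deterministic sign: largest-magnitude loading positive per axis
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            rel[:, j] = -rel[:, j]
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return WarpScores(partial, rel, frac, vt.T, list(proc.ids))


class RelativeWarps(TransformerMixin, BaseEstimator):
    """GPA + thin-plate-spline relative warps as an sklearn transformer.

    ``fit`` runs generalized Procrustes analysis on an (n, k, 2) array (or a
    list of :class:`LandmarkConfiguration`), builds the warp basis at the
    consensus and the relative-warp axes.  ``transform`` aligns configurations
    to the fitted consensus and returns their relative-warp scores.

    Parameters
    ----------
    alpha : float, default 0.0
        Bending-energy weighting exponent for partial warps (0 gives
        unweighted scores, whose principal components coincide with those of
        the aligned coordinates).
    tol, max_iter : GPA convergence controls.

    Attributes
    ----------
    consensus_ : (k, 2) mean shape.
    centroid_sizes_ : (n,) centroid sizes of the training specimens.
    basis_ : fitted :class:`WarpBasis`.
    scores_ : fitted :class:`WarpScores` of the training specimens.
    explained_variance_ratio_ : per-axis variance fractions.
    n_axes_ : number of relative warps with nonzero variance.
    """

    def __init__(self, alpha: float = 0.0, tol: float = 1e-10, max_iter: int = 100):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _as_array(X):
        if isinstance(X, np.ndarray):
            return np.asarray(X, float), None
        arr = np.stack([c.points for c in X])
        return arr, [c.id for c in X]

    def fit(self, X, y=None):
        arr, ids = self._as_array(X)
        self.gpa_ = gpa(arr, tol=self.tol, max_iter=self.max_iter, ids=ids)
        self.consensus_ = self.gpa_.consensus
        self.centroid_sizes_ = self.gpa_.centroid_sizes
        self.basis_ = warp_basis(self.consensus_, alpha=self.alpha)
        self.scores_ = warp_scores(self.gpa_, self.basis_)
        self.explained_variance_ratio_ = self.scores_.variance_fraction
        self.n_axes_ = self.scores_.n_axes
        return self

    def transform(self, X):
        arr, ids = self._as_array(X)
        n = arr.shape[0]
        aligned = np.empty_like(arr)
        sizes = np.empty(n)
        for i in range(n):
            centered = arr[i] - arr[i].mean(axis=0)
            sizes[i] = centroid_size(centered)
            aligned[i] = _rotate_onto(centered / sizes[i], self.consensus_)
        proc = ProcrustesResult(self.consensus_, aligned, sizes,
                                ids or [f"specimen_{i}" for i in range(n)], 0, True)
        ws = warp_scores(proc, self.basis_)
        # project onto the fitted axes, not refit ones
        centered = ws.partial - self.scores_.partial.mean(axis=0)
        return centered @ self.scores_.loadings

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_.relative
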