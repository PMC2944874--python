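"""Simulated half-sib common-garden studies with known genetic ground truth.

The generator reproduces the statistical skeleton of the hatchery
experiment: three strain-specific crossing designs (12 + 30 + 28 = 70
full/half-sib families), additive + dam + family + residual variance on
latent traits, latent shape effects applied along fixed orthonormal
non-affine deformation axes of a 13-landmark salmonid template, allometric
weight-length growth, and nuisance digitization transforms (random rotation,
translation, scale, plus landmark noise).

True heritability of latent trait t is V_a / (V_a + V_m + V_c + V_e) by
construction, so every pipeline stage can be checked by parameter recovery.
Randomness flows from one root seed through named child streams, so adding a
stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometrics import LandmarkConfiguration, centroid_size, warp_basis, write_tps
from .pedigree import (
    CrossDesign,
    IndividualRecord,
    RelationshipMatrix,
    additive_relationship_matrix,
    default_designs,
    pedigree_from_design,
    write_pedigree_csv,
)

__all__ = [
    "VarianceSpec",
    "SimulationParams",
    "SimulatedDataset",
    "default_mean_shape",
    "default_effect_basis",
    "simulate_breeding_values",
    "simulate_study",
    "write_fixture_study",
]


# 13-landmark salmonid outline in body-length units (snout at the origin,
# following the standard ordering: snout, neurocranium, dorsal-fin origin and
# insertion, adipose, dorsal and middle and ventral caudal points, anal-fin
# insertion and origin, pelvic, pectoral, maxillary).
_MEAN_SHAPE = np.array([
    [0.00, 0.000],
    [0.18, 0.100],
    [0.38, 0.130],
    [0.52, 0.110],
    [0.72, 0.080],
    [0.86, 0.050],
    [0.93, 0.000],
    [0.86, -0.050],
    [0.76, -0.070],
    [0.66, -0.090],
    [0.45, -0.110],
    [0.22, -0.090],
    [0.12, -0.030],
])


def default_mean_shape() -> np.ndarray:
    """Centered, unit-centroid-size 13-landmark template."""
    X = _MEAN_SHAPE - _MEAN_SHAPE.mean(axis=0)
    return X / centroid_size(X)


def default_effect_basis(mean_shape: np.ndarray | None = None, q: int = 2) -> np.ndarray:
    """q orthonormal non-affine deformation directions (2k vectors).

    The lowest-bending-energy principal warps of the template are used as
    large-scale deformations (body depth, caudal-peduncle shape); trait t
    displaces the y (t even) or x (t odd) coordinates along warp t//2.
    They are orthonormal, centered, and carry no affine component.
    """
    X = default_mean_shape() if mean_shape is None else mean_shape
    basis = warp_basis(X)
    pw = basis.principal_warps[:, ::-1]  # ascending bending energy
    k = X.shape[0]
    out = np.zeros((q, 2 * k))
    for t in range(q):
        col = pw[:, t // 2]
        out[t, (t % 2)::2] = col
    return out


@dataclass
class VarianceSpec:
    """Variance components of one latent trait."""

    V_a: float = 0.5
    V_m: float = 0.05
    V_c: float = 0.05
    V_e: float = 0.40

    def __post_init__(self):
        for nm in ("V_a", "V_m", "V_c", "V_e"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be non-negative")

    @property
    def V_p(self) -> float:
        return self.V_a + self.V_m + self.V_c + self.V_e

    @property
    def h2(self) -> float:
        return self.V_a / self.V_p if self.V_p > 0 else 0.0

    @property
    def m2(self) -> float:
        return self.V_m / self.V_p if self.V_p > 0 else 0.0


@dataclass
class SimulationParams:
    """Stated world of the simulated study.

    Defaults follow the experiment the generator emulates: the three printed
    crossing designs (70 families), three sampling periods, latent shape
    traits with h2 = 0.5 and small dam/family components, allometric
    exponent b = 3.1 with log10-scale noise sd 0.05, and digitization
    nuisance (arbitrary image rotation/translation/scale) with landmark noise
    small relative to biological shape variation.
    """

    designs: list[CrossDesign] = field(default_factory=default_designs)
    offspring_per_family: int = 8
    n_periods: int = 3
    shape_variance: list[VarianceSpec] = field(
        default_factory=lambda: [VarianceSpec(), VarianceSpec()])
    effect_basis: np.ndarray | None = None   # q x 2k orthonormal rows; default warp axes
    effect_scale: float = 0.03          # Procrustes units per latent-trait sd
    length_variance: VarianceSpec = field(
        default_factory=lambda: VarianceSpec(V_a=50.0, V_m=5.0, V_c=5.0, V_e=40.0))
    strain_length_means: dict = field(
        default_factory=lambda: {"Assinica": 105.0, "IronRiver": 90.0, "Siskiwit": 95.0})
    period_growth: tuple = (1.0, 1.35, 1.6)    # multiplicative length growth
    allometry_intercept: float = -5.0          # log10 g at log10 mm = 0
    allometry_slope: float = 3.1
    allometry_log_sd: float = 0.05
    landmark_noise_sd: float = 0.002           # unit-centroid-size coordinates
    period_drift: float = 0.01                 # consensus drift per period (3rd warp axis)
    nuisance_transforms: bool = True
    scale_range: tuple = (80.0, 140.0)         # digitizing units per unit shape
    maturation_rate: float = 0.2               # periods 2-3 only
    seed: int = 0


@dataclass
class SimulatedDataset:
    pedigree: list[IndividualRecord]
    relationship: RelationshipMatrix
    breeding_values: np.ndarray        # n_offspring x n_latent_traits
    landmarks: dict                    # period -> list[LandmarkConfiguration]
    phenotypes: pd.DataFrame
    truth: dict
    params: SimulationParams


def simulate_breeding_values(A, V_a: float, seed_or_rng) -> np.ndarray:
    """One MVN(0, A * V_a) draw via a PSD eigenvalue square root."""
    if V_a < 0:
        raise ValueError("V_a must be non-negative")
    Av = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if V_a == 0:
        return np.zeros(Av.shape[0])
    w, U = np.linalg.eigh(Av)
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(Av.shape[0])
    return U @ (np.sqrt(w * V_a) * z)


def _family_effects(levels: np.ndarray, var: float, rng) -> np.ndarray:
    codes, uniq = pd.factorize(levels)
    draws = rng.standard_normal(len(uniq)) * np.sqrt(var)
    return draws[codes]


def _latent_trait(A, spec: VarianceSpec, dam, family, rng) -> tuple[np.ndarray, np.ndarray]:
    """Breeding value + dam + family parts of a latent trait (env added per period)."""
    bv = simulate_breeding_values(A, spec.V_a, rng)
    de = _family_effects(dam, spec.V_m, rng)
    fe = _family_effects(family, spec.V_c, rng)
    return bv, bv + de + fe


def simulate_study(params: SimulationParams | None = None) -> SimulatedDataset:
    """Generate a complete study: pedigree, landmarks per period, phenotypes."""
    params = params or SimulationParams()
    root = np.random.SeedSequence(params.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("genetics", "shape", "size", "nuisance", "maturation", "development"),
        root.spawn(6))}

    pedigree: list[IndividualRecord] = []
    for d in params.designs:
        pedigree.extend(pedigree_from_design(d, params.offspring_per_family))
    rel = additive_relationship_matrix(pedigree)
    off = [r for r in pedigree if r.sire is not None]
    ids = [r.id for r in off]
    A_off = rel.subset(ids)
    dam = np.array([r.dam for r in off])
    sire = np.array([r.sire for r in off])
    family = np.array([f"{r.sire}x{r.dam}" for r in off])
    strain = np.array([r.strain for r in off])
    n = len(off)

    gen = streams["genetics"]
    q = len(params.shape_variance)
    if params.effect_basis is not None:
        basis = np.asarray(params.effect_basis, float)
        k2 = 2 * default_mean_shape().shape[0]
        if basis.ndim != 2 or basis.shape != (q, k2):
            raise ValueError(f"effect_basis must be {q} x {k2} (one row per latent trait)")
        if not np.allclose(basis @ basis.T, np.eye(q), atol=1e-8):
            raise ValueError("effect_basis rows must be orthonormal")
    else:
        basis = default_effect_basis(q=q)
    bvs = np.empty((n, q))
    latents = []
    for t, spec in enumerate(params.shape_variance):
        bv, lat = _latent_trait(A_off, spec, dam, family, gen)
        bvs[:, t] = bv
        latents.append(lat)
    len_spec = params.length_variance
    len_bv, len_lat = _latent_trait(A_off, len_spec, dam, family, gen)

    mean_shape = default_mean_shape()
    k = mean_shape.shape[0]
    drift_dir = default_effect_basis(q=q + 1)[q] if params.period_drift else None

    shp = streams["shape"]
    szr = streams["size"]
    nui = streams["nuisance"]
    mat = streams["maturation"]
    dev = streams["development"]

    # family-level development rate (ATU) and dam-level egg diameter
    fam_levels = pd.unique(family)
    hatch_days = np.clip(np.round(50 + 3 * dev.standard_normal(len(fam_levels))), 35, 70)
    atu_by_fam = dict(zip(fam_levels, 9.5 * hatch_days))
    dam_levels = pd.unique(dam)
    egg_by_dam = dict(zip(dam_levels, 4.0 + 0.2 * dev.standard_normal(len(dam_levels))))

    landmarks: dict[int, list[LandmarkConfiguration]] = {}
    pheno_rows = []
    for period in range(1, params.n_periods + 1):
        configs = []
        consensus_p = mean_shape.copy()
        if drift_dir is not None:
            consensus_p = consensus_p + (period - 1) * params.period_drift * drift_dir.reshape(k, 2)
        env_shape = [shp.standard_normal(n) * np.sqrt(s.V_e) for s in params.shape_variance]
        env_len = szr.standard_normal(n) * np.sqrt(len_spec.V_e)
        log_w_noise = szr.standard_normal(n) * params.allometry_log_sd
        mature = np.zeros(n, bool)
        if period >= 2:
            mature = mat.random(n) < params.maturation_rate
        growth = params.period_growth[period - 1]
        for i, rec in enumerate(off):
            shape = consensus_p.copy()
            for t in range(q):
                z = latents[t][i] + env_shape[t][i]
                shape = shape + params.effect_scale * z * basis[t].reshape(k, 2)
            shape = shape + shp.standard_normal((k, 2)) * params.landmark_noise_sd
            if params.nuisance_transforms:
                th = nui.uniform(-np.pi, np.pi)
                R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
                sc = nui.uniform(*params.scale_range)
                tr = nui.uniform(-50, 50, size=2)
                shape = shape @ R.T * sc + tr
            configs.append(LandmarkConfiguration(f"{rec.id}_p{period}", shape))
            L = (params.strain_length_means[rec.strain] + len_lat[i] + env_len[i]) * growth
            L = max(L, 20.0)
            W = 10 ** (params.allometry_intercept + params.allometry_slope * np.log10(L)
                       + log_w_noise[i])
            pheno_rows.append({
                "id": rec.id, "family": family[i], "sire": sire[i], "dam": dam[i],
                "strain": rec.strain, "period": period,
                "length_mm": round(float(L), 6), "weight_g": round(float(W), 6),
                "mature": bool(mature[i]),
                "atu": round(float(atu_by_fam[family[i]]), 6),
                "egg_diameter_mm": round(float(egg_by_dam[dam[i]]), 6),
            })
        landmarks[period] = configs

    truth = {
        "seed": params.seed,
        "n_families": sum(d.n_families for d in params.designs),
        "n_offspring": n,
        "shape_traits": [
            {"V_a": s.V_a, "V_m": s.V_m, "V_c": s.V_c, "V_e": s.V_e,
             "h2": s.h2, "m2": s.m2} for s in params.shape_variance],
        "length": {"V_a": len_spec.V_a, "V_m": len_spec.V_m, "V_c": len_spec.V_c,
                   "V_e": len_spec.V_e, "h2": len_spec.h2, "m2": len_spec.m2},
        "effect_scale": params.effect_scale,
        "allometry": {"a": params.allometry_intercept, "b": params.allometry_slope,
                      "log_sd": params.allometry_log_sd},
        "landmark_noise_sd": params.landmark_noise_sd,
    }
    phen = pd.DataFrame(pheno_rows)
    return SimulatedDataset(pedigree, rel, bvs, landmarks, phen, truth, params)


def write_fixture_study(params: SimulationParams | None = None, out_dir=".") -> Path:
    """Write a complete fixture tree: TPS per period, pedigree.csv,
    phenotypes.csv, truth.json.  Byte-identical across runs with one seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_study(params)
    for period, configs in ds.landmarks.items():
        write_tps(configs, out / f"landmarks_period{period}.tps")
    write_pedigree_csv(ds.pedigree, out / "pedigree.csv")
    ds.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
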