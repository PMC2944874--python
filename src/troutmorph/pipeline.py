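"""End-to-end analysis pipeline.

Stages: morphometrics per sampling period (one pooled relative-warp space per
period) -> condition factor -> per-strain and pooled heritability per trait ->
MANOVA / MANCOVA -> leave-one-out DFA -> repeated measures on family means.
Every stage is deterministic given the configuration and its seeds; report
tables are written as headered CSV plus a plain-text summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .growth import WeightLengthRegression
from .morphometrics import RelativeWarps, read_tps
from .mvstats import dfa_loo, mancova_interaction, manova_wilks, repeated_measures_family_means
from .pedigree import additive_relationship_matrix, read_pedigree_csv
from .quantgen import AnimalModelREML, lrt_component, strain_comparison
from .simulate import SimulationParams, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    Exactly one of ``tps_paths`` (with ``pedigree_path``/``phenotype_path``)
    or ``simulate`` must be given.
    """

    tps_paths: dict | None = None          # period -> path
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    simulate: SimulationParams | None = None
    n_warps: int = 6                       # leading relative warps analyzed
    random_terms: tuple = ("additive",)
    pooled_random_terms: tuple = ("additive",)
    dfa_subsample: int = 4
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if (self.simulate is None) == (self.tps_paths is None):
            raise ValueError("give either input paths or a simulate block, not both")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None and not isinstance(d["simulate"], SimulationParams):
            d["simulate"] = SimulationParams(**d["simulate"])
        return cls(**d)


def _config_hash(config: RunConfig) -> str:
    txt = repr(config).encode()
    return hashlib.sha256(txt).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        ds = simulate_study(config.simulate)
        return ds.pedigree, ds.relationship, ds.landmarks, ds.phenotypes
    pedigree = read_pedigree_csv(config.pedigree_path)
    rel = additive_relationship_matrix(pedigree)
    landmarks = {int(p): read_tps(path) for p, path in sorted(config.tps_paths.items())}
    phen = pd.read_csv(config.phenotype_path,
                       dtype={"id": str, "family": str, "sire": str, "dam": str})
    return pedigree, rel, landmarks, phen


def _herit_row(y, X, rel_sub, label: dict, random_terms, dam=None, family=None) -> dict:
    full = AnimalModelREML(random_terms=random_terms).fit(
        X, y, relationship=rel_sub, dam=dam, family=family)
    reduced_terms = tuple(t for t in random_terms if t != "additive")
    red = AnimalModelREML(random_terms=reduced_terms, compute_se=False).fit(
        X, y, relationship=None, dam=dam, family=family)
    lrt = lrt_component(full, red)
    row = dict(label)
    row.update({
        "V_a": full.varcomp_.get("additive", 0.0),
        "V_m": full.varcomp_.get("dam", 0.0),
        "V_c": full.varcomp_.get("family", 0.0),
        "V_e": full.varcomp_["residual"],
        "h2": full.h2_, "h2_se": full.h2_se_,
        "m2": full.m2_, "m2_se": full.m2_se_,
        "loglik": full.loglik_, "lrt_stat": lrt.statistic, "lrt_p": lrt.p,
        "converged": full.converged_,
    })
    return row


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run the full analysis; returns a dict of report tables (DataFrames).

    With ``config.out_dir`` set, tables are also written as CSV together with
    a run log (version, config hash, seeds) and a plain-text summary.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    rng_seed = config.seed
    pedigree, rel, landmarks, phen = _load_inputs(config)
    periods = sorted(landmarks)
    report: dict[str, pd.DataFrame] = {}

    # --- morphometrics: one relative-warp space per period
    warp_tables = []
    scores_by_period = {}
    for period in periods:
        configs = landmarks[period]
        rw = RelativeWarps().fit(configs)
        ids = [c.id.rsplit("_p", 1)[0] for c in configs]
        m = min(config.n_warps, rw.scores_.relative.shape[1])
        tab = pd.DataFrame(rw.scores_.relative[:, :m],
                           columns=[f"RW{j + 1}" for j in range(m)])
        tab.insert(0, "id", ids)
        tab["log10_centroid_size"] = np.log10(rw.centroid_sizes_)
        scores_by_period[period] = tab
        for j in range(rw.explained_variance_ratio_.size):
            warp_tables.append({"period": period, "warp": j + 1,
                                "variance_fraction": rw.explained_variance_ratio_[j]})
    report["warp_variance"] = pd.DataFrame(warp_tables)

    # --- condition factor from the pooled weight-length regression
    wl = WeightLengthRegression().fit(phen)
    phen = phen.copy()
    phen["K_n"] = wl.condition(phen)
    report["weight_length"] = pd.DataFrame(
        [{"intercept": wl.intercept_, "slope": wl.slope_, "n": wl.n_}])

    # --- merge scores with phenotypes
    merged = {}
    for period in periods:
        sub = phen[phen["period"] == period].merge(scores_by_period[period], on="id")
        merged[period] = sub

    traits = [f"RW{j + 1}" for j in range(config.n_warps)] + ["length_mm", "weight_g", "K_n"]
    if "atu" in phen.columns:
        traits.append("atu")

    # --- heritability per strain x period x trait, plus pooled
    herit_rows, pooled_rows = [], []
    for period in periods:
        sub = merged[period]
        use_mature = period >= 2 and "mature" in sub and sub["mature"].nunique() > 1
        for strain, s in sub.groupby("strain"):
            rel_sub = rel.subset(list(s["id"]))
            X = np.ones((len(s), 1))
            if use_mature and s["mature"].nunique() > 1:
                X = np.column_stack([X, s["mature"].astype(float)])
            for trait in traits:
                y = s[trait].to_numpy(float)
                if trait not in s or np.var(y) <= 0:
                    continue
                herit_rows.append(_herit_row(
                    y, X, rel_sub, {"period": period, "strain": strain, "trait": trait},
                    config.random_terms, dam=s["dam"].to_numpy(),
                    family=s["family"].to_numpy()))
        # pooled across strains: strain as fixed effect
        rel_sub = rel.subset(list(sub["id"]))
        strains = sorted(sub["strain"].unique())
        X = np.ones((len(sub), 1))
        for st in strains[1:]:
            X = np.column_stack([X, (sub["strain"] == st).astype(float)])
        if use_mature:
            X = np.column_stack([X, sub["mature"].astype(float)])
        for trait in traits:
            y = sub[trait].to_numpy(float)
            if np.var(y) <= 0:
                continue
            pooled_rows.append(_herit_row(
                y, X, rel_sub, {"period": period, "trait": trait},
                config.pooled_random_terms, dam=sub["dam"].to_numpy(),
                family=sub["family"].to_numpy()))
    report["heritability_by_strain"] = pd.DataFrame(herit_rows)
    report["heritability_pooled"] = pd.DataFrame(pooled_rows)

    # --- multivariate strain statistics
    wilks_rows, dfa_tables, strain_rows = [], [], []
    rw_cols = [f"RW{j + 1}" for j in range(config.n_warps)]
    for period in periods:
        sub = merged[period]
        man = manova_wilks(sub[rw_cols].to_numpy(), sub["strain"].to_numpy())
        wilks_rows.append({"period": period, "test": "MANOVA", "wilks_lambda": man.wilks_lambda,
                           "F": man.F, "df1": man.df1, "df2": man.df2, "p": man.p})
        anc = mancova_interaction(sub[rw_cols].to_numpy(), sub["strain"].to_numpy(),
                                  sub["log10_centroid_size"].to_numpy())
        wilks_rows.append({"period": period, "test": "MANCOVA interaction",
                           "wilks_lambda": anc.wilks_lambda, "F": anc.F,
                           "df1": anc.df1, "df2": anc.df2, "p": anc.p})
        conf = dfa_loo(sub[rw_cols].to_numpy(), sub["strain"].to_numpy(),
                       families=sub["family"].to_numpy(),
                       per_family_subsample=config.dfa_subsample, seed=rng_seed + period)
        conf = conf.reset_index(names="original_strain")
        conf.insert(0, "period", period)
        dfa_tables.append(conf)
        for trait in traits:
            res = strain_comparison(sub, trait)
            for row in res["comparisons"].itertuples(index=False):
                strain_rows.append({"period": period, "trait": trait,
                                    "strain_a": row.strain_a, "strain_b": row.strain_b,
                                    "diff": row.diff, "p_tukey": row.p_tukey})
        # egg diameter is a dam-level trait (one value per dam): compare
        # strains on dam means with Tukey's HSD
        if period == periods[0] and "egg_diameter_mm" in sub.columns:
            from scipy.stats import tukey_hsd

            dams = sub.groupby(["dam", "strain"], as_index=False)["egg_diameter_mm"].first()
            strains = sorted(dams["strain"].unique())
            groups = [dams.loc[dams["strain"] == s, "egg_diameter_mm"].to_numpy()
                      for s in strains]
            hsd = tukey_hsd(*groups)
            for i, a in enumerate(strains):
                for j in range(i + 1, len(strains)):
                    strain_rows.append({
                        "period": period, "trait": "egg_diameter_mm",
                        "strain_a": a, "strain_b": strains[j],
                        "diff": float(groups[i].mean() - groups[j].mean()),
                        "p_tukey": float(hsd.pvalue[i, j])})
    report["wilks_tests"] = pd.DataFrame(wilks_rows)
    report["dfa_confusion"] = pd.concat(dfa_tables, ignore_index=True)
    report["strain_comparisons"] = pd.DataFrame(strain_rows)

    # --- repeated measures on family means of each leading warp
    rm_rows = []
    if len(periods) >= 2:
        long = pd.concat([merged[p].assign(period=p) for p in periods], ignore_index=True)
        for col in rw_cols:
            tab = repeated_measures_family_means(long, col)
            for row in tab.itertuples(index=False):
                rm_rows.append({"warp": col, "effect": row.effect, "F": row.F,
                                "df1": row.df1, "df2": row.df2, "p": row.p})
    report["repeated_measures"] = pd.DataFrame(rm_rows)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in report.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        log = {"version": __version__, "config_hash": _config_hash(config),
               "seed": config.seed, "n_periods": len(periods)}
        (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
        lines = [f"troutmorph {__version__} run {_config_hash(config)}"]
        for name, tab in report.items():
            lines.append(f"\n== {name} ({len(tab)} rows) ==")
            lines.append(tab.head(20).to_string(index=False))
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
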