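"""Breeding designs, pedigrees, and additive genetic relationship matrices.

A pedigree is an ordered list of :class:`IndividualRecord` in which parents
precede their offspring.  The additive (numerator) relationship matrix A is
computed by the tabular method; its entries are twice the kinship
coefficients, so non-inbred parent-offspring pairs have A = 0.5 and paternal
half-sibs A = 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndividualRecord",
    "CrossDesign",
    "RelationshipMatrix",
    "build_cross_design",
    "pedigree_from_design",
    "additive_relationship_matrix",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

UNKNOWN = None


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree entry. ``sire``/``dam`` are ``None`` for founders."""

    id: str
    sire: str | None = None
    dam: str | None = None
    strain: str = ""
    sex: str = ""
    generation: int = 0


@dataclass
class CrossDesign:
    """A mating design: which sire is crossed to which dam.

    ``kind`` is one of ``"nested"`` (each dam has exactly one sire),
    ``"partial-factorial"`` (each dam mated to a fixed number of sires) or
    ``"split-egg-lot"`` (nested, but a stated subset of dams is mated to a
    second sire).
    """

    n_dams: int
    n_sires: int
    matings: list[tuple[str, str]] = field(default_factory=list)
    kind: str = "nested"
    strain: str = ""

    @property
    def n_families(self) -> int:
        return len(set(self.matings))

    @property
    def sires(self) -> list[str]:
        out: list[str] = []
        for s, _ in self.matings:
            if s not in out:
                out.append(s)
        return out

    @property
    def dams(self) -> list[str]:
        out: list[str] = []
        for _, d in self.matings:
            if d not in out:
                out.append(d)
        return out

    def validate(self) -> None:
        if len(set(self.matings)) != len(self.matings):
            raise ValueError("duplicate (sire, dam) mating pair in design")
        if len(self.sires) > self.n_sires:
            raise ValueError("more sires used than declared")
        if len(self.dams) > self.n_dams:
            raise ValueError("more dams used than declared")


class DesignInfeasibleError(ValueError):
    """A mating rule cannot be satisfied by the given dam/sire counts."""


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A over an ordered list of ids."""

    ids: list[str]
    values: np.ndarray

    def loc(self, i: str, j: str) -> float:
        ii, jj = self.ids.index(i), self.ids.index(j)
        return float(self.values[ii, jj])

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


def _labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def build_cross_design(
    n_dams: int,
    n_sires: int,
    kind: str = "nested",
    *,
    dams_per_sire: tuple[int, int] | int = (2, 3),
    sires_per_dam: int = 2,
    n_split_dams: int = 0,
    strain: str = "",
    dam_prefix: str = "D",
    sire_prefix: str = "S",
    seed: int | None = None,
) -> CrossDesign:
    """Construct a mating design of the given kind.

    Parameters
    ----------
    dams_per_sire
        For nested / split-egg-lot designs: allowed range (lo, hi) of dams per
        sire, or a single int.  Dams are dealt to sires deterministically in
        label order unless ``seed`` is given, in which case the assignment of
        which sires receive the extra dam is shuffled.
    sires_per_dam
        Partial-factorial only: number of sires each dam is mated to.
    n_split_dams
        Split-egg-lot only: number of dams whose egg lots are split and
        fertilized by a second sire.
    """
    if n_dams <= 0 or n_sires <= 0:
        raise ValueError("dam and sire counts must be positive")
    dams = _labels(dam_prefix, n_dams)
    sires = _labels(sire_prefix, n_sires)
    rng = np.random.default_rng(seed) if seed is not None else None

    if isinstance(dams_per_sire, int):
        lo = hi = dams_per_sire
    else:
        lo, hi = dams_per_sire

    if kind in ("nested", "split-egg-lot"):
        if not (n_sires * lo <= n_dams <= n_sires * hi):
            raise DesignInfeasibleError(
                f"cannot deal {n_dams} dams to {n_sires} sires at "
                f"{lo}-{hi} dams each (need between {n_sires * lo} and {n_sires * hi} dams)"
            )
        # number of sires taking hi dams
        n_hi = n_dams - n_sires * lo
        if hi > lo and n_hi % (hi - lo):
            raise DesignInfeasibleError("dam total not expressible with the allowed per-sire counts")
        n_hi = n_hi // (hi - lo) if hi > lo else 0
        counts = [hi] * n_hi + [lo] * (n_sires - n_hi)
        if rng is not None:
            rng.shuffle(counts)
        matings: list[tuple[str, str]] = []
        pos = 0
        for s, c in zip(sires, counts):
            for d in dams[pos : pos + c]:
                matings.append((s, d))
            pos += c
        if kind == "split-egg-lot" and n_split_dams:
            if n_split_dams > n_dams:
                raise DesignInfeasibleError("more split dams than dams")
            if n_sires < 2:
                raise DesignInfeasibleError("splitting egg lots needs a second sire")
            first_sire = dict((d, s) for s, d in matings)
            split = list(dams[:n_split_dams])
            if rng is not None:
                split = list(rng.choice(dams, size=n_split_dams, replace=False))
            for d in split:
                # second sire: next sire in label order that is not the first
                others = [s for s in sires if s != first_sire[d]]
                k = dams.index(d) % len(others)
                matings.append((others[k], d))
    elif kind == "partial-factorial":
        total = n_dams * sires_per_dam
        if total % n_sires:
            raise DesignInfeasibleError(
                f"{n_dams} dams x {sires_per_dam} sires each = {total} matings "
                f"not divisible among {n_sires} sires"
            )
        per_sire = total // n_sires
        if per_sire > n_dams:
            raise DesignInfeasibleError("each sire would need more dams than exist")
        # biregular bipartite assignment: sire i takes consecutive dams mod n_dams
        matings = []
        pos = 0
        for s in sires:
            block = [dams[(pos + j) % n_dams] for j in range(per_sire)]
            if len(set(block)) != len(block):
                raise DesignInfeasibleError("per-sire dam block wraps onto itself")
            matings.extend((s, d) for d in block)
            pos += per_sire
        if len(set(matings)) != len(matings):
            raise DesignInfeasibleError("partial-factorial layout repeats a sire-dam pair")
    else:
        raise ValueError(f"unknown design kind: {kind!r}")

    design = CrossDesign(n_dams=n_dams, n_sires=n_sires, matings=matings, kind=kind, strain=strain)
    design.validate()
    return design


def siskiwit_design() -> CrossDesign:
    """12 dams x 5 sires nested, 12 families."""
    return build_cross_design(12, 5, "nested", dams_per_sire=(2, 3), strain="Siskiwit",
                              dam_prefix="SkD", sire_prefix="SkS")


def assinica_design() -> CrossDesign:
    """15 dams x 10 sires partial factorial (sire x 3 dams, dam x 2 sires), 30 families."""
    return build_cross_design(15, 10, "partial-factorial", sires_per_dam=2,
                              dams_per_sire=3, strain="Assinica",
                              dam_prefix="AsD", sire_prefix="AsS")


def iron_river_design() -> CrossDesign:
    """20 dams x 10 sires, eggs of 8 dams split to a second sire, 28 families."""
    return build_cross_design(20, 10, "split-egg-lot", dams_per_sire=2, n_split_dams=8,
                              strain="IronRiver", dam_prefix="IrD", sire_prefix="IrS")


def default_designs() -> list[CrossDesign]:
    """The three hatchery-strain designs (12 + 30 + 28 = 70 families)."""
    return [siskiwit_design(), assinica_design(), iron_river_design()]


def pedigree_from_design(
    design: CrossDesign, offspring_per_family: int, *, offspring_prefix: str | None = None
) -> list[IndividualRecord]:
    """Expand a design into founder + offspring records, parents first."""
    if offspring_per_family < 1:
        raise ValueError("offspring_per_family must be >= 1")
    design.validate()
    pre = offspring_prefix if offspring_prefix is not None else (design.strain or "F")
    records = [
        IndividualRecord(d, strain=design.strain, sex="F", generation=0) for d in design.dams
    ] + [
        IndividualRecord(s, strain=design.strain, sex="M", generation=0) for s in design.sires
    ]
    for f, (s, d) in enumerate(design.matings, start=1):
        for o in range(1, offspring_per_family + 1):
            records.append(
                IndividualRecord(
                    f"{pre}_f{f}_o{o}", sire=s, dam=d, strain=design.strain, generation=1
                )
            )
    return records


def _check_ordered(pedigree: list[IndividualRecord]) -> dict[str, int]:
    index: dict[str, int] = {}
    for pos, rec in enumerate(pedigree):
        if rec.id in index:
            raise ValueError(f"duplicate id {rec.id!r}")
        for parent in (rec.sire, rec.dam):
            if parent is not None and parent not in index:
                raise KeyError(
                    f"parent {parent!r} of {rec.id!r} not defined earlier in the pedigree"
                )
        index[rec.id] = pos
    return index


def additive_relationship_matrix(pedigree: list[IndividualRecord]) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    A[i,i] = 1 + F_i with F_i = 0.5 * A[sire_i, dam_i]; A[i,j] for j < i is
    0.5 * (A[j, sire_i] + A[j, dam_i]).  Unknown parents contribute 0
    (founders are taken unrelated and non-inbred).
    """
    index = _check_ordered(pedigree)
    n = len(pedigree)
    A = np.zeros((n, n))
    for i, rec in enumerate(pedigree):
        si = index[rec.sire] if rec.sire is not None else -1
        di = index[rec.dam] if rec.dam is not None else -1
        for j in range(i):
            a = 0.0
            if si >= 0:
                a += A[j, si]
            if di >= 0:
                a += A[j, di]
            A[i, j] = A[j, i] = 0.5 * a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix([r.id for r in pedigree], A)


def pedigree_to_frame(pedigree: list[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in pedigree],
            "sire": [r.sire if r.sire is not None else "NA" for r in pedigree],
            "dam": [r.dam if r.dam is not None else "NA" for r in pedigree],
            "strain": [r.strain for r in pedigree],
            "sex": [r.sex for r in pedigree],
            "generation": [r.generation for r in pedigree],
        }
    )


def write_pedigree_csv(pedigree: list[IndividualRecord], path) -> None:
    pedigree_to_frame(pedigree).to_csv(path, index=False)


def read_pedigree_csv(path) -> list[IndividualRecord]:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            IndividualRecord(
                id=str(row.id),
                sire=None if row.sire in ("NA", "") else str(row.sire),
                dam=None if row.dam in ("NA", "") else str(row.dam),
                strain=str(getattr(row, "strain", "")),
                sex=str(getattr(row, "sex", "")),
                generation=int(getattr(row, "generation", 0)),
            )
        )
    _check_ordered(records)
    return records
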