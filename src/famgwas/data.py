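"""Core in-memory containers shared by every analysis stage.

The common currency of the package is :class:`GenotypeMatrix`, a samples ×
variants dosage matrix (0/1/2 alt-allele counts, NaN for a missing call)
carrying per-variant metadata, plus :class:`Pedigree`, the family structure
of the cohort. Phenotypes travel as plain :class:`pandas.DataFrame` tables
keyed by ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "Pedigree", "validate_pedigree"]

#: Columns required in the variant metadata table.
VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples × variants dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows).
    variants : pandas.DataFrame
        One row per variant (columns ``chrom, pos, id, ref, alt``), in
        matrix column order. Positions are 1-based; within a chromosome
        they must be non-decreasing.
    dosages : ndarray of float, shape (n_samples, n_variants)
        Alt-allele dosages in {0, 1, 2}; missing calls are ``nan``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows"
            )
        if p != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but {p} dosage columns"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad} outside {{0,1,2,missing}}")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions on {chrom} are not sorted")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant id {variant_id!r}")
        return self.dosages[:, idx[0]]

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        """New matrix restricted to ``variant_ids`` (original order kept)."""
        keep = set(variant_ids)
        mask = self.variants["id"].isin(keep).to_numpy()
        return GenotypeMatrix(
            self.sample_ids, self.variants.loc[mask], self.dosages[:, mask]
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        """New matrix restricted to ``sample_ids`` (original order kept)."""
        keep = set(sample_ids)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep]
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.variants,
            self.dosages[idx, :],
        )


@dataclass
class Pedigree:
    """Family structure: parents and offspring with sire/dam links.

    ``table`` columns: ``sample_id, sire_id, dam_id, family_id, role`` where
    role is ``"parent"`` or ``"offspring"``; parents have no sire/dam (None).
    A dam shared between two families (maternal half sibs) appears once,
    under the first family she mothers.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "sire_id", "dam_id", "family_id", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table lacks columns {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        validate_pedigree(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def parents(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "parent"]

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "offspring"]

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.table["family_id"]:
            seen.setdefault(f, None)
        return list(seen)

    def family_of(self) -> dict[str, str]:
        """sample_id -> family_id map."""
        return dict(zip(self.table["sample_id"], self.table["family_id"]))

    def members(self, family_id: str) -> list[str]:
        """All samples (parents + offspring) recorded under a family.

        A shared dam is listed only under her first family; use parent
        links for exact membership when that matters.
        """
        return self.table.loc[
            self.table["family_id"] == family_id, "sample_id"
        ].tolist()


def validate_pedigree(table: pd.DataFrame) -> None:
    """Check pedigree invariants; raise ``ValueError`` on violation.

    Every offspring's sire and dam must exist as parents, full sibs share a
    family id, and no sample can be its own ancestor.
    """
    ids = set(table["sample_id"])
    if len(ids) != len(table):
        raise ValueError("duplicate sample ids in pedigree")
    parent_ids = set(table.loc[table["role"] == "parent", "sample_id"])
    links: dict[str, tuple] = {}
    for row in table.itertuples(index=False):
        if row.role == "offspring":
            if row.sire_id not in parent_ids:
                raise ValueError(
                    f"offspring {row.sample_id} has unknown sire {row.sire_id}"
                )
            if row.dam_id not in parent_ids:
                raise ValueError(
                    f"offspring {row.sample_id} has unknown dam {row.dam_id}"
                )
        links[row.sample_id] = (row.sire_id, row.dam_id)
    # acyclicity: walk parent links from each sample
    for start in links:
        stack, seen = [start], set()
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            for p in links.get(cur, (None, None)):
                if p == start:
                    raise ValueError(f"sample {start} is its own ancestor")
                if p is not None and not (isinstance(p, float) and np.isnan(p)):
                    stack.append(p)
    # full sibs share a family id
    sib_groups: dict[tuple, set] = {}
    for row in table.itertuples(index=False):
        if row.role == "offspring":
            sib_groups.setdefault((row.sire_id, row.dam_id), set()).add(
                row.family_id
            )
    for (sire, dam), fams in sib_groups.items():
        if len(fams) > 1:
            raise ValueError(
                f"full sibs of {sire} x {dam} span families {sorted(fams)}"
            )
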