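"""Synthetic family cohorts: pedigrees, Mendelian genotypes, phenotypes.

The generator emulates the study design this package targets: a small
aquaculture broodstock cohort of ~7 full-sib families from 13 parents
(7 sires, 6 dams, one dam shared between two families so one family is a
maternal half-sib family), ~105 offspring, biallelic SNP genotypes with a
realistic minor-allele-frequency spectrum, per-variant missingness, and
quantitative traits built from an additive dosage model with a Gaussian
family random intercept:

    y = a + tau_family + sum_j beta_j * dosage_j + e,
    tau ~ N(0, var_family),  e ~ N(0, var_resid).

All randomness flows from a single integer seed through independently
spawned :class:`numpy.random.Generator` streams, so each stage is
reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree

__all__ = [
    "TraitModelSpec",
    "QCFixtureProfile",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "inject_missingness",
    "make_qc_fixture",
    "study_pedigree_profile",
    "study_qc_profile",
    "study_trait_specs",
]

#: Study design constants: 7 families, 105 progeny, 13 parents.
STUDY_N_FAMILIES = 7
STUDY_N_OFFSPRING = 105


@dataclass
class TraitModelSpec:
    """Parameters of the additive trait model with a family random effect.

    ``beta`` maps variant ids to fixed effects in trait units per
    alt-allele dosage; ``var_family`` and ``var_resid`` are the variance
    components (trait units squared).
    """

    intercept: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    var_family: float = 1.0
    var_resid: float = 1.0
    name: str = "trait"

    def __post_init__(self) -> None:
        if self.var_family < 0:
            raise ValueError("var_family must be non-negative")
        if self.var_resid < 0:
            raise ValueError("var_resid must be non-negative")


@dataclass
class QCFixtureProfile:
    """Marginal stratum counts for a constructed QC fixture.

    The four strata partition the variants by their fate in the QC
    cascade (MAF filter, then call-rate filter, then completeness).
    """

    n_variants_total: int
    n_low_maf: int
    n_low_callrate: int
    n_with_missing: int
    n_complete: int
    seed: int = 0

    def __post_init__(self) -> None:
        parts = (
            self.n_low_maf
            + self.n_low_callrate
            + self.n_with_missing
            + self.n_complete
        )
        if parts != self.n_variants_total:
            raise ValueError(
                "stratum counts "
                f"{self.n_low_maf} + {self.n_low_callrate} + "
                f"{self.n_with_missing} + {self.n_complete} = {parts} "
                f"!= n_variants_total = {self.n_variants_total}"
            )


def study_pedigree_profile() -> dict:
    """Arguments reproducing the study pedigree (7 families, 105 progeny)."""
    return dict(
        n_families=STUDY_N_FAMILIES,
        offspring_per_family=[15] * STUDY_N_FAMILIES,
        half_sib_dam_sharing=True,
    )


def study_qc_profile(seed: int = 0) -> QCFixtureProfile:
    """Stratum counts matching the study's variant QC cascade."""
    return QCFixtureProfile(
        n_variants_total=15233,
        n_low_maf=2065,
        n_low_callrate=7882,
        n_with_missing=3028,
        n_complete=2258,
        seed=seed,
    )


def study_trait_specs(causal: dict[str, dict[str, float]] | None = None):
    """Default trait models for the four study phenotypes.

    Intercepts and variance components are chosen to resemble harvest-age
    sea bream: weight ~800 g at harvest, tag weight ~50 g at 205 days post
    hatching, fat ~10%, length/width ratio ~2.7; family variance is a
    sizeable fraction of the total, as expected for growth traits in a
    cohort selected for between-family weight variation.

    Parameters
    ----------
    causal : optional map trait name -> {variant_id: beta}
    """
    causal = causal or {}
    base = {
        "fat_pct": TraitModelSpec(10.0, {}, 1.0, 4.0, name="fat_pct"),
        "weight_g": TraitModelSpec(800.0, {}, 10000.0, 22500.0, name="weight_g"),
        "tag_weight_g": TraitModelSpec(50.0, {}, 25.0, 100.0, name="tag_weight_g"),
        "length_width": TraitModelSpec(2.7, {}, 0.01, 0.04, name="length_width"),
    }
    for trait, betas in causal.items():
        base[trait].beta = dict(betas)
    return base


def simulate_pedigree(
    n_families: int,
    offspring_per_family,
    half_sib_dam_sharing: bool = True,
    seed: int = 0,
) -> Pedigree:
    """Build a multi-family pedigree of full sibs, optionally one half-sib pair.

    Each family has its own sire; each family has its own dam except that,
    when ``half_sib_dam_sharing`` is on (and there are >= 2 families), the
    first two families share a dam, making their offspring maternal half
    sibs and reducing the parent count by one (7 families -> 13 parents).

    Deterministic given ``seed`` (the seed only fixes offspring id order,
    kept for interface symmetry with the other simulators).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if np.isscalar(offspring_per_family):
        offspring_per_family = [int(offspring_per_family)] * n_families
    offspring_per_family = [int(k) for k in offspring_per_family]
    if len(offspring_per_family) != n_families:
        raise ValueError(
            f"expected {n_families} offspring counts, "
            f"got {len(offspring_per_family)}"
        )
    if any(k < 1 for k in offspring_per_family):
        raise ValueError("offspring counts must be >= 1")

    rows = []
    share = half_sib_dam_sharing and n_families >= 2
    dam_of: dict[int, str] = {}
    n_dams = 0
    for i in range(n_families):
        if share and i == 1:
            dam_of[i] = dam_of[0]
        else:
            n_dams += 1
            dam_of[i] = f"D{n_dams}"
    fam_names = [f"F{i + 1}" for i in range(n_families)]
    for i in range(n_families):
        rows.append((f"S{i + 1}", None, None, fam_names[i], "parent"))
    seen_dams = set()
    for i in range(n_families):
        if dam_of[i] not in seen_dams:
            seen_dams.add(dam_of[i])
            rows.append((dam_of[i], None, None, fam_names[i], "parent"))
    child = 0
    for i in range(n_families):
        for _ in range(offspring_per_family[i]):
            child += 1
            rows.append(
                (f"O{child:03d}", f"S{i + 1}", dam_of[i], fam_names[i], "offspring")
            )
    table = pd.DataFrame(
        rows, columns=["sample_id", "sire_id", "dam_id", "family_id", "role"]
    )
    return Pedigree(table)


def _variant_table(n_variants: int, rng: np.random.Generator, n_chrom: int = 24):
    """Random variant metadata spread over ``n_chrom`` chromosomes."""
    chrom_idx = np.sort(rng.integers(0, n_chrom, size=n_variants))
    pos = np.empty(n_variants, dtype=int)
    for c in range(n_chrom):
        mask = chrom_idx == c
        k = int(mask.sum())
        if k:
            draw = np.unique(rng.integers(1, 30_000_000, size=2 * k + 8))
            while draw.size < k:  # vanishingly unlikely
                draw = np.unique(
                    np.concatenate([draw, rng.integers(1, 30_000_000, size=k)])
                )
            pos[mask] = np.sort(rng.choice(draw, size=k, replace=False))
    chroms = [f"chr{c + 1}" for c in chrom_idx]
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n_variants)
    alt = (ref + rng.integers(1, 4, size=n_variants)) % 4
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "id": [f"{c}:{p}" for c, p in zip(chroms, pos)],
            "ref": bases[ref],
            "alt": bases[alt],
        }
    )


def simulate_genotypes(
    pedigree: Pedigree,
    n_variants: int,
    maf_sampler=None,
    seed: int = 0,
    ld_block_size: int | None = None,
    n_chrom: int = 24,
) -> GenotypeMatrix:
    """Draw founder genotypes from Hardy–Weinberg and drop them down the pedigree.

    Founders (parents) receive two haplotype alleles per locus, each
    Bernoulli at a frequency drawn from ``maf_sampler`` (default: uniform
    on [0.01, 0.5]). Each offspring receives one uniformly chosen allele
    per parent per locus. With ``ld_block_size`` set, the choice of
    transmitted parental haplotype is made once per block of that many
    consecutive loci instead of per locus, creating within-family LD;
    default is independent transmission.
    """
    if pedigree.table.empty:
        raise ValueError("empty pedigree")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        freqs = rng.uniform(0.01, 0.5, size=n_variants)
    else:
        freqs = np.asarray(maf_sampler(rng, n_variants), dtype=float)

    variants = _variant_table(n_variants, rng, n_chrom=n_chrom)
    samples = pedigree.sample_ids
    hap = {}  # sample -> (h1, h2) arrays of 0/1
    for pid in pedigree.parents["sample_id"]:
        hap[pid] = (
            (rng.random(n_variants) < freqs).astype(np.int8),
            (rng.random(n_variants) < freqs).astype(np.int8),
        )

    if ld_block_size is None:
        block_id = np.arange(n_variants)
    else:
        block_id = np.zeros(n_variants, dtype=int)
        b = 0
        prev = None
        for j, chrom in enumerate(variants["chrom"]):
            if prev is not None and (chrom != prev or (j % ld_block_size == 0)):
                b += 1
            block_id[j] = b
            prev = chrom
    n_blocks = int(block_id.max()) + 1

    def gamete(parent_id: str) -> np.ndarray:
        h1, h2 = hap[parent_id]
        pick = rng.integers(0, 2, size=n_blocks)[block_id]
        return np.where(pick == 0, h1, h2)

    for row in pedigree.offspring.itertuples(index=False):
        hap[row.sample_id] = (gamete(row.sire_id), gamete(row.dam_id))

    dosages = np.vstack([hap[s][0] + hap[s][1] for s in samples]).astype(float)
    return GenotypeMatrix(samples, variants, dosages)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    ped: Pedigree,
    spec: TraitModelSpec,
    seed: int = 0,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Phenotypes from the additive dosage model with a family random intercept.

    By default only offspring are phenotyped (the study measures progeny);
    pass ``samples`` to override. Missing dosages at causal variants
    contribute their per-variant mean effect (mean imputation), keeping the
    generator total-variance bookkeeping intact under missingness.

    Returns a DataFrame with columns ``sample_id, family_id, <spec.name>``.
    """
    for vid in spec.beta:
        if vid not in set(gm.variant_ids):
            raise KeyError(f"beta keys unknown variant {vid!r}")
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = ped.offspring["sample_id"].tolist()
    fam_of = ped.family_of()
    missing = [s for s in samples if s not in fam_of]
    if missing:
        raise KeyError(f"samples absent from pedigree: {missing[:3]}")
    families = sorted({fam_of[s] for s in samples})
    tau = dict(
        zip(families, rng.normal(0.0, math.sqrt(spec.var_family), len(families)))
    )
    row_of = {s: i for i, s in enumerate(gm.sample_ids)}
    y = np.full(len(samples), float(spec.intercept))
    for vid, beta in spec.beta.items():
        col = gm.column(vid)
        col = np.where(np.isnan(col), np.nanmean(col), col)
        y += beta * np.array([col[row_of[s]] for s in samples])
    y += np.array([tau[fam_of[s]] for s in samples])
    y += rng.normal(0.0, math.sqrt(spec.var_resid), len(samples))
    return pd.DataFrame(
        {
            "sample_id": samples,
            "family_id": [fam_of[s] for s in samples],
            spec.name: y,
        }
    )


def inject_missingness(
    gm: GenotypeMatrix, per_variant_rates, seed: int = 0
) -> GenotypeMatrix:
    """Set each genotype missing independently at its variant's rate (MCAR)."""
    rates = np.broadcast_to(
        np.asarray(per_variant_rates, dtype=float), (gm.n_variants,)
    )
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("missingness rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.dosages.shape) < rates[None, :]
    dosages = gm.dosages.copy()
    dosages[mask] = np.nan
    return GenotypeMatrix(gm.sample_ids, gm.variants.copy(), dosages)


def _common_column(
    n: int, n_missing: int, rng: np.random.Generator
) -> np.ndarray:
    """A dosage column with folded MAF ~0.3-0.5 and ``n_missing`` missing calls."""
    m = n - n_missing
    n_hom_alt = m // 3
    n_het = m // 3 + (m % 3)
    col = np.concatenate(
        [
            np.full(n_hom_alt, 2.0),
            np.full(n_het, 1.0),
            np.zeros(m - n_hom_alt - n_het),
            np.full(n_missing, np.nan),
        ]
    )
    rng.shuffle(col)
    return col


def make_qc_fixture(
    profile: QCFixtureProfile,
    n_samples: int = 118,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
) -> GenotypeMatrix:
    """Construct a genotype matrix with exact QC-cascade stratum counts.

    Strata (each verified by construction against the filter definitions,
    applied in cascade order):

    1. ``n_low_maf`` variants with folded MAF < ``maf_min`` over non-missing
       calls (half of them carry one missing call, so permuting the cascade
       changes the counts);
    2. of the rest, ``n_low_callrate`` with call rate < ``callrate_min``;
    3. of the rest, ``n_with_missing`` with >= 1 missing call (call rate
       still >= ``callrate_min``);
    4. ``n_complete`` fully observed.

    Deterministic given ``profile.seed``.
    """
    n = int(n_samples)
    if n < 3:
        raise ValueError("need at least 3 samples")
    # feasibility at these thresholds
    low_cr_miss = math.floor(n * (1 - callrate_min)) + 1
    if (n - low_cr_miss) / n >= callrate_min:  # numeric guard
        low_cr_miss += 1
    if profile.n_low_callrate > 0 and n - low_cr_miss < 1:
        raise ValueError(
            "callrate_min too low: no observed call would remain in the "
            "low-call-rate stratum"
        )
    if profile.n_with_missing > 0 and (n - 1) / n < callrate_min:
        raise ValueError(
            f"with {n} samples a single missing call already drops call rate "
            f"below {callrate_min}; the missing-but-passing stratum is empty"
        )

    rng = np.random.default_rng(profile.seed)
    cols = []
    labels = []
    for k in range(profile.n_low_maf):
        # singleton het -> folded MAF 1/(2m) < maf_min (monomorphic when the
        # cohort is too small for that); odd ones get one missing call so
        # that reordering the cascade changes the counts
        n_miss = 1 if (k % 2 and n >= 2) else 0
        m = n - n_miss
        n_het = 1 if 1.0 / (2 * m) < maf_min else 0
        col = np.concatenate(
            [np.ones(n_het), np.zeros(m - n_het), np.full(n_miss, np.nan)]
        )
        rng.shuffle(col)
        cols.append(col)
        labels.append("low_maf")
    for _ in range(profile.n_low_callrate):
        cols.append(_common_column(n, low_cr_miss, rng))
        labels.append("low_callrate")
    for _ in range(profile.n_with_missing):
        cols.append(_common_column(n, 1, rng))
        labels.append("with_missing")
    for _ in range(profile.n_complete):
        cols.append(_common_column(n, 0, rng))
        labels.append("complete")

    order = rng.permutation(profile.n_variants_total)
    dosages = np.column_stack([cols[i] for i in order])
    variants = _variant_table(profile.n_variants_total, rng)
    sample_ids = [f"X{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages)
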