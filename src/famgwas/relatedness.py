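"""Pedigree verification: robust kinship, PCA, hierarchical clustering.

Pairwise kinship uses the robust between-family estimator built from
shared-heterozygote and opposite-homozygote counts,

    phi_ij = (N_het,het - 2 * N_opp_hom) / (N_het(i) + N_het(j)),

computed over pairwise-complete loci. On this scale duplicated samples
(or monozygotic twins) score 0.5, full sibs ~0.25, and unrelated pairs
~0. Family labels are verified by comparing each sample's mean kinship
to its claimed family against every other family; mislabeled samples are
reassigned, unplaceable ones flagged for exclusion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .data import GenotypeMatrix, Pedigree

__all__ = [
    "kinship_matrix",
    "pca_embed",
    "hierarchical_cluster",
    "verify_families",
]


def kinship_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise robust kinship over pairwise-complete genotypes.

    A pair in which neither member carries a heterozygous call at any
    shared locus has an undefined coefficient and is reported as NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples for pairwise kinship")
    D = gm.dosages
    valid = ~np.isnan(D)
    het = (D == 1.0) & valid
    hom_ref = (D == 0.0) & valid
    hom_alt = (D == 2.0) & valid

    hetf = het.astype(float)
    validf = valid.astype(float)
    n_hh = hetf @ hetf.T  # both heterozygous
    n_opp = hom_ref.astype(float) @ hom_alt.astype(float).T
    n_opp = n_opp + n_opp.T  # opposite homozygotes, either orientation
    het_i = hetf @ validf.T  # het sites of i among pairwise-complete loci
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    phi = (phi + phi.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(phi, index=gm.sample_ids, columns=gm.sample_ids)


def _imputed_standardized(gm: GenotypeMatrix) -> np.ndarray:
    D = gm.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(D, axis=0)
    idx = np.where(np.isnan(D))
    D[idx] = np.take(means, idx[1])
    D -= D.mean(axis=0)
    sd = D.std(axis=0)
    keep = sd > 0
    return D[:, keep] / sd[keep]


def pca_embed(gm: GenotypeMatrix, n_components: int = 2):
    """Principal-component coordinates of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant; constant variants are
    dropped before standardization. Returns ``(coords, explained_var)``
    with component variances in non-increasing order.
    """
    Z = _imputed_standardized(gm)
    if Z.shape[1] == 0:
        raise ValueError("constant genotype matrix: no variation to embed")
    k = min(n_components, min(Z.shape))
    if n_components > min(gm.n_samples, gm.n_variants):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(Z)
    return coords, pca.explained_variance_


def hierarchical_cluster(
    gm: GenotypeMatrix, n_clusters: int, method: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering on Euclidean dosage distances.

    Missing dosages are mean-imputed. Cutting the dendrogram yields
    ``n_clusters`` integer labels (1-based, scipy convention).
    """
    if n_clusters > gm.n_samples:
        raise ValueError("n_clusters exceeds the number of samples")
    D = gm.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(D, axis=0)
    idx = np.where(np.isnan(D))
    D[idx] = np.take(means, idx[1])
    tree = linkage(D, method=method, metric="euclidean")
    return fcluster(tree, t=n_clusters, criterion="maxclust")


def verify_families(
    kin: pd.DataFrame, ped: Pedigree, reassign_margin: float = 0.05
) -> pd.DataFrame:
    """Check claimed family labels against mean pairwise kinship.

    Verification targets offspring: parents are the pedigree anchors (a
    dam shared between two families genuinely belongs to both, so her
    label is not testable). For each offspring, mean kinship to every
    family's other offspring is computed. The claim is *confirmed* when
    the claimed family beats every other family by ``reassign_margin``;
    the sample is *reassigned* when a different family wins by the
    margin; otherwise it is *unassigned*. Reassigned and unassigned
    samples are the exclusion candidates. A family with no other
    offspring falls back to its parents' kinship, with a warning.
    """
    fam_of = ped.family_of()
    roles = dict(zip(ped.table["sample_id"], ped.table["role"]))
    samples = [s for s in kin.index if roles.get(s) == "offspring"]
    unknown = [s for s in kin.index if s not in fam_of]
    if unknown:
        raise ValueError(f"samples missing from pedigree: {unknown[:3]}")
    families = ped.family_ids
    in_kin = set(kin.index)
    members = {
        f: [
            s
            for s in ped.members(f)
            if roles.get(s) == "offspring" and s in in_kin
        ]
        for f in families
    }
    parent_members = {
        f: [
            s
            for s in ped.members(f)
            if roles.get(s) == "parent" and s in in_kin
        ]
        for f in families
    }
    K = kin.to_numpy()
    pos = {s: i for i, s in enumerate(kin.index)}

    rows = []
    for s in samples:
        claimed = fam_of[s]
        means = {}
        for f in families:
            others = [m for m in members[f] if m != s]
            if not others:
                others = parent_members[f]
                warnings.warn(
                    f"family {f} has no other offspring than {s}; "
                    "comparing by parent kinship only"
                )
            if not others:
                means[f] = np.nan
                continue
            vals = np.array([K[pos[s], pos[m]] for m in others])
            vals = vals[~np.isnan(vals)]
            means[f] = float(vals.mean()) if vals.size else np.nan
        claimed_mean = means.get(claimed, np.nan)
        other = {f: v for f, v in means.items() if f != claimed}
        finite_other = {f: v for f, v in other.items() if np.isfinite(v)}
        best_other, best_other_mean = (None, -np.inf)
        if finite_other:
            best_other = max(finite_other, key=lambda f: finite_other[f])
            best_other_mean = finite_other[best_other]

        if np.isfinite(claimed_mean) and (
            claimed_mean >= best_other_mean + reassign_margin
        ):
            status, assigned = "confirmed", claimed
        elif best_other is not None and best_other_mean >= reassign_margin + max(
            claimed_mean if np.isfinite(claimed_mean) else -np.inf,
            max(
                (v for f, v in finite_other.items() if f != best_other),
                default=-np.inf,
            ),
        ):
            status, assigned = "reassigned", best_other
        else:
            status, assigned = "unassigned", None
        rows.append(
            {
                "sample_id": s,
                "claimed_family": claimed,
                "assigned_family": assigned,
                "status": status,
                "mean_kin_claimed": claimed_mean,
                "mean_kin_best_other": (
                    best_other_mean if np.isfinite(best_other_mean) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
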