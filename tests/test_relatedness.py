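"""Robust kinship, PCA, clustering, and family verification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from famgwas import simdata
from famgwas.data import GenotypeMatrix, Pedigree
from famgwas.relatedness import (
    hierarchical_cluster,
    kinship_matrix,
    pca_embed,
    verify_families,
)


@pytest.fixture(scope="module")
def cohort():
    ped = simdata.simulate_pedigree(7, 15, half_sib_dam_sharing=True, seed=31)
    gm = simdata.simulate_genotypes(
        ped, 5000, maf_sampler=lambda rng, k: np.full(k, 0.3), seed=32
    )
    return ped, gm


def test_duplicate_sample_kinship_half(cohort):
    ped, gm = cohort
    dup = GenotypeMatrix(
        gm.sample_ids[:2] + ["copy"],
        gm.variants,
        np.vstack([gm.dosages[:2], gm.dosages[1:2]]),
    )
    kin = kinship_matrix(dup)
    assert kin.loc[dup.sample_ids[1], "copy"] == pytest.approx(0.5)


def test_unrelated_founders_near_zero(cohort):
    ped, gm = cohort
    sires = ped.parents[ped.parents["sample_id"].str.startswith("S")]
    founders = gm.subset_samples(sires["sample_id"].tolist())
    kin = kinship_matrix(founders)
    off_diag = kin.to_numpy()[np.triu_indices(founders.n_samples, k=1)]
    assert abs(np.nanmean(off_diag)) < 0.02


def test_full_sibs_near_quarter(cohort):
    ped, gm = cohort
    fam_of = ped.family_of()
    offs = ped.offspring["sample_id"].tolist()
    kin = kinship_matrix(gm.subset_samples(offs))
    vals = []
    for i, a in enumerate(offs):
        for b in offs[i + 1 :]:
            if fam_of[a] == fam_of[b]:
                vals.append(kin.loc[a, b])
    assert np.mean(vals) == pytest.approx(0.25, abs=0.03)


def test_kinship_symmetric_and_order_invariant(cohort):
    _, gm = cohort
    small = gm.subset_samples(gm.sample_ids[:10])
    kin = kinship_matrix(small)
    np.testing.assert_allclose(kin.to_numpy(), kin.to_numpy().T)
    kin_rev = kinship_matrix(
        GenotypeMatrix(small.sample_ids[::-1], small.variants,
                       small.dosages[::-1])
    )
    np.testing.assert_allclose(
        kin.to_numpy(),
        kin_rev.loc[kin.index, kin.columns].to_numpy(),
    )


def test_kinship_undefined_pair_nan():
    D = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 2.0], [1.0, 1.0, 1.0]])
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2, 3], "id": ["a", "b", "c"],
         "ref": "A", "alt": "G"}
    )
    kin = kinship_matrix(GenotypeMatrix(["x", "y", "z"], variants, D))
    assert np.isnan(kin.loc["x", "y"])  # no het in either member
    assert np.isfinite(kin.loc["x", "z"])


# ---------------------------------------------------------------------------
# PCA / clustering
# ---------------------------------------------------------------------------
def _clone_matrix(rng, n_groups=3, per=5, p=60):
    protos = rng.integers(0, 3, size=(n_groups, p)).astype(float)
    protos[:, 0] = [0, 1, 2][:n_groups]  # guarantee polymorphism
    D = np.repeat(protos, per, axis=0)
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, p + 1), "ref": "A", "alt": "G",
         "id": [f"v{j}" for j in range(p)]}
    )
    ids = [f"g{g}_{i}" for g in range(n_groups) for i in range(per)]
    labels = np.repeat(np.arange(n_groups), per)
    return GenotypeMatrix(ids, variants, D), labels


def test_pca_separates_two_clusters(rng):
    gm, labels = _clone_matrix(rng, n_groups=2)
    coords, var = pca_embed(gm, 2)
    a = coords[labels == 0, 0]
    b = coords[labels == 1, 0]
    assert max(a.max(), b.max()) - min(a.min(), b.min()) > 0
    assert (a.max() < b.min()) or (b.max() < a.min())
    assert np.all(np.diff(var) <= 1e-9)


def test_pca_preserves_total_variance(rng):
    ped = simdata.simulate_pedigree(3, 6, seed=1)
    gm = simdata.simulate_genotypes(
        ped, 40, maf_sampler=lambda r, k: np.full(k, 0.4), seed=2
    )
    k = min(gm.n_samples, gm.n_variants)
    coords, var = pca_embed(gm, k)
    # total variance of standardized matrix = sum of component variances
    from famgwas.relatedness import _imputed_standardized

    Z = _imputed_standardized(gm)
    total = Z.var(axis=0, ddof=1).sum()
    assert var.sum() == pytest.approx(total, rel=1e-8)


def test_pca_rejects_constant_matrix():
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2], "id": ["a", "b"], "ref": "A",
         "alt": "G"}
    )
    gm = GenotypeMatrix(["x", "y", "z"], variants, np.ones((3, 2)))
    with pytest.raises(ValueError, match="constant"):
        pca_embed(gm, 1)


def test_family_structure_beats_permuted_labels(cohort, rng):
    ped, gm = cohort
    offs = gm.subset_samples(ped.offspring["sample_id"].tolist())
    fam = ped.offspring["family_id"].to_numpy()
    coords, _ = pca_embed(offs, 2)
    s_true = silhouette_score(coords, fam)
    s_perm = silhouette_score(coords, rng.permutation(fam))
    assert s_true > s_perm

    labels = hierarchical_cluster(offs, 7)
    assert adjusted_rand_score(fam, labels) > adjusted_rand_score(
        rng.permutation(fam), labels
    )


def test_cluster_duplicates_and_clones(rng):
    gm, labels = _clone_matrix(rng, n_groups=3)
    got = hierarchical_cluster(gm, 3)
    assert adjusted_rand_score(labels, got) == 1.0
    for cut in (2, 3, 4):
        cl = hierarchical_cluster(gm, cut)
        # clones always share a cluster at any cut coarser than group count
        if cut <= 3:
            for g in range(3):
                assert len(set(cl[labels == g])) == 1


def test_cluster_rejects_too_many_clusters(rng):
    gm, _ = _clone_matrix(rng, n_groups=2, per=2)
    with pytest.raises(ValueError):
        hierarchical_cluster(gm, 10)


# ---------------------------------------------------------------------------
# family verification
# ---------------------------------------------------------------------------
def test_correct_labels_all_confirmed(cohort):
    ped, gm = cohort
    kin = kinship_matrix(gm)
    report = verify_families(kin, ped, reassign_margin=0.05)
    assert (report["status"] == "confirmed").all()


def _planted_cohort(swap=False, unrelated=False, seed=77):
    ped = simdata.simulate_pedigree(7, 12, half_sib_dam_sharing=True,
                                    seed=seed)
    gm = simdata.simulate_genotypes(
        ped, 3000, maf_sampler=lambda rng, k: np.full(k, 0.3), seed=seed + 1
    )
    table = ped.table.copy()
    victims = []
    if swap:
        # move one F4 offspring's label to F5 (families without shared dam)
        f4 = table[(table.family_id == "F4") & (table.role == "offspring")]
        v = f4["sample_id"].iloc[0]
        f5 = table[(table.family_id == "F5") & (table.role == "offspring")]
        table.loc[table.sample_id == v, ["sire_id", "dam_id", "family_id"]] = (
            f5["sire_id"].iloc[0], f5["dam_id"].iloc[0], "F5",
        )
        victims.append(("reassigned", v, "F4"))
    dosages = gm.dosages.copy()
    if unrelated:
        u = table[(table.family_id == "F6") & (table.role == "offspring")][
            "sample_id"
        ].iloc[-1]
        i = gm.sample_ids.index(u)
        rng2 = np.random.default_rng(seed + 5)
        dosages[i] = rng2.binomial(2, 0.3, gm.n_variants).astype(float)
        victims.append(("unassigned", u, None))
    gm2 = GenotypeMatrix(gm.sample_ids, gm.variants, dosages)
    return Pedigree(table), gm2, victims


def test_swapped_offspring_reassigned():
    ped, gm, victims = _planted_cohort(swap=True)
    kin = kinship_matrix(gm)
    report = verify_families(kin, ped).set_index("sample_id")
    _, v, true_family = victims[0]
    assert report.loc[v, "status"] == "reassigned"
    assert report.loc[v, "assigned_family"] == true_family


def test_unrelated_sample_unassigned():
    ped, gm, victims = _planted_cohort(unrelated=True)
    kin = kinship_matrix(gm)
    report = verify_families(kin, ped).set_index("sample_id")
    _, u, _ = victims[0]
    assert report.loc[u, "status"] == "unassigned"


def test_study_scenario_flags_exactly_two():
    """One mislabeled + one unplaceable sample among 7 families -> 2 flags."""
    ped, gm, victims = _planted_cohort(swap=True, unrelated=True)
    kin = kinship_matrix(gm)
    report = verify_families(kin, ped)
    flagged = set(report.loc[report["status"] != "confirmed", "sample_id"])
    assert flagged == {v for _, v, _ in victims}
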