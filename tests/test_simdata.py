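"""Generator correctness: pedigrees, Mendelian transmission, trait model."""

import numpy as np
import pandas as pd
import pytest

from famgwas import simdata
from famgwas.data import GenotypeMatrix
from famgwas.qc import minor_allele_frequency


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------
def test_study_profile_counts(study_pedigree):
    ped = study_pedigree
    assert len(ped.parents) == 13
    assert len(ped.offspring) == 105
    assert len(ped.family_ids) == 7
    # one dam mothers two families -> a maternal half-sib pair exists
    dams = ped.offspring.groupby("dam_id")["family_id"].nunique()
    assert (dams == 2).sum() == 1


def test_minimal_pedigree():
    ped = simdata.simulate_pedigree(1, [1], half_sib_dam_sharing=False)
    assert len(ped.parents) == 2
    assert len(ped.offspring) == 1


@pytest.mark.parametrize("bad", [(0, [5]), (2, [3, 0]), (2, [3])])
def test_pedigree_rejects_bad_counts(bad):
    n_fam, counts = bad
    with pytest.raises(ValueError):
        simdata.simulate_pedigree(n_fam, counts)


@pytest.mark.parametrize(
    "n_fam,counts,share",
    [(3, [2, 5, 1], True), (5, 4, False), (7, [15] * 7, True)],
)
def test_pedigree_invariants_independent_walk(n_fam, counts, share):
    """Brute-force validator: parent links resolve, sibs share families,
    no sample is its own ancestor."""
    ped = simdata.simulate_pedigree(n_fam, counts, share, seed=5)
    t = ped.table
    parents = set(t.loc[t.role == "parent", "sample_id"])
    links = {r.sample_id: (r.sire_id, r.dam_id)
             for r in t.itertuples(index=False)}
    for r in t.itertuples(index=False):
        if r.role == "offspring":
            assert r.sire_id in parents and r.dam_id in parents
        seen, frontier = set(), [r.sample_id]
        while frontier:
            cur = frontier.pop()
            for p in links.get(cur, (None, None)):
                if p is not None:
                    assert p != r.sample_id
                    if p not in seen:
                        seen.add(p)
                        frontier.append(p)
    fams = t[t.role == "offspring"].groupby(["sire_id", "dam_id"])[
        "family_id"
    ].nunique()
    assert (fams == 1).all()


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------
def test_mendelian_transmission(study_pedigree):
    gm = simdata.simulate_genotypes(study_pedigree, 300, seed=3)
    row = {s: i for i, s in enumerate(gm.sample_ids)}
    possible = {
        (0, 0): {0}, (0, 2): {1}, (2, 0): {1}, (2, 2): {2},
        (0, 1): {0, 1}, (1, 0): {0, 1}, (2, 1): {1, 2}, (1, 2): {1, 2},
        (1, 1): {0, 1, 2},
    }
    seen_certain = 0
    for r in study_pedigree.offspring.itertuples(index=False):
        s = gm.dosages[row[r.sire_id]]
        d = gm.dosages[row[r.dam_id]]
        o = gm.dosages[row[r.sample_id]]
        for j in range(gm.n_variants):
            assert o[j] in possible[(int(s[j]), int(d[j]))]
            if (s[j], d[j]) in ((0, 0), (2, 0), (0, 2)):
                seen_certain += 1
    assert seen_certain > 0  # the certainty cases were actually exercised


def test_founder_allele_frequency():
    ped = simdata.simulate_pedigree(30, 1, half_sib_dam_sharing=False)
    n_loci = 10_000
    gm = simdata.simulate_genotypes(
        ped, n_loci, maf_sampler=lambda rng, k: np.full(k, 0.3), seed=9
    )
    founders = gm.subset_samples(ped.parents["sample_id"].tolist())
    f_hat = founders.dosages.mean() / 2.0
    n_alleles = 2 * founders.n_samples * n_loci
    se = np.sqrt(0.3 * 0.7 / n_alleles)
    assert abs(f_hat - 0.3) < 3 * se


def test_genotypes_reject_empty_pedigree():
    with pytest.raises(ValueError):
        simdata.simulate_genotypes(
            simdata.simulate_pedigree(1, [1]).__class__(
                pd.DataFrame(columns=["sample_id", "sire_id", "dam_id",
                                      "family_id", "role"])
            ),
            10,
        )


def test_genotypes_deterministic(study_pedigree):
    a = simdata.simulate_genotypes(study_pedigree, 50, seed=4)
    b = simdata.simulate_genotypes(study_pedigree, 50, seed=4)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    assert a.variant_ids == b.variant_ids


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------
def test_phenotype_degenerate_and_linear(study_pedigree):
    gm = simdata.simulate_genotypes(study_pedigree, 20, seed=6)
    spec0 = simdata.TraitModelSpec(3.5, {}, 0.0, 0.0, name="t")
    ph = simdata.simulate_phenotypes(gm, study_pedigree, spec0, seed=1)
    assert np.allclose(ph["t"], 3.5)

    vid = gm.variant_ids[0]
    spec1 = simdata.TraitModelSpec(0.0, {vid: 5.0}, 0.0, 0.0, name="t")
    ph1 = simdata.simulate_phenotypes(gm, study_pedigree, spec1, seed=1)
    dos = dict(zip(gm.sample_ids, gm.column(vid)))
    y2 = ph1.loc[[dos[s] == 2 for s in ph1["sample_id"]], "t"]
    y0 = ph1.loc[[dos[s] == 0 for s in ph1["sample_id"]], "t"]
    if len(y2) and len(y0):
        assert np.isclose(y2.iloc[0] - y0.iloc[0], 10.0)


def test_variance_decomposition_moments():
    """Between/within family variance components recovered by ANOVA moments."""
    ped = simdata.simulate_pedigree(200, 10, half_sib_dam_sharing=False)
    gm = simdata.simulate_genotypes(ped, 2, seed=2)
    spec = simdata.TraitModelSpec(0.0, {}, 4.0, 1.0, name="t")
    withins, betweens = [], []
    for seed in (21, 22, 23, 24):  # average out single-draw sampling noise
        ph = simdata.simulate_phenotypes(gm, ped, spec, seed=seed)
        g = ph.groupby("family_id")["t"]
        within = g.apply(lambda v: v.var(ddof=1)).mean()
        withins.append(within)
        betweens.append(g.mean().var(ddof=1) - within / 10)
    assert abs(np.mean(withins) - 1.0) < 0.15
    assert abs(np.mean(betweens) - 4.0) < 0.6


def test_phenotype_rejects_negative_variance():
    with pytest.raises(ValueError):
        simdata.TraitModelSpec(0.0, {}, -1.0, 1.0)


def test_phenotype_rejects_unknown_beta_key(study_pedigree):
    gm = simdata.simulate_genotypes(study_pedigree, 5, seed=6)
    spec = simdata.TraitModelSpec(0.0, {"nope": 1.0}, 1.0, 1.0)
    with pytest.raises(KeyError):
        simdata.simulate_phenotypes(gm, study_pedigree, spec)


def test_phenotype_reproducible(study_cohort):
    a = simdata.simulate_phenotypes(
        study_cohort["gm"], study_cohort["ped"], study_cohort["spec"], seed=13
    )
    pd.testing.assert_frame_equal(a, study_cohort["phenos"])


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------
def test_missingness_edges(study_pedigree):
    gm = simdata.simulate_genotypes(study_pedigree, 10, seed=8)
    same = simdata.inject_missingness(gm, 0.0, seed=1)
    np.testing.assert_array_equal(same.dosages, gm.dosages)
    rates = np.zeros(10)
    rates[3] = 1.0
    holey = simdata.inject_missingness(gm, rates, seed=1)
    assert np.isnan(holey.dosages[:, 3]).all()
    assert not np.isnan(holey.dosages[:, 4]).any()
    with pytest.raises(ValueError):
        simdata.inject_missingness(gm, 1.5)


def test_missingness_rate_binomial():
    ped = simdata.simulate_pedigree(100, 10, half_sib_dam_sharing=False)
    gm = simdata.simulate_genotypes(ped, 5, seed=3)
    out = simdata.inject_missingness(gm, 0.2, seed=4)
    frac = np.isnan(out.dosages).mean()
    n = out.dosages.size
    se = np.sqrt(0.2 * 0.8 / n)
    assert abs(frac - 0.2) < 3 * se


# ---------------------------------------------------------------------------
# QC fixture
# ---------------------------------------------------------------------------
def _classify(col, maf_min, callrate_min):
    callrate = 1 - np.isnan(col).mean()
    maf = minor_allele_frequency(col)
    if maf < maf_min:
        return "low_maf"
    if callrate < callrate_min:
        return "low_callrate"
    if np.isnan(col).any():
        return "with_missing"
    return "complete"


def test_tiny_fixture_hand_checkable():
    profile = simdata.QCFixtureProfile(4, 1, 1, 1, 1, seed=7)
    gm = simdata.make_qc_fixture(profile, n_samples=3, callrate_min=0.5)
    got = sorted(
        _classify(gm.dosages[:, j], 0.05, 0.5) for j in range(4)
    )
    assert got == ["complete", "low_callrate", "low_maf", "with_missing"]


def test_fixture_strata_match_filter_definitions():
    profile = simdata.QCFixtureProfile(60, 13, 21, 16, 10, seed=3)
    gm = simdata.make_qc_fixture(profile, n_samples=118)
    counts = {}
    for j in range(gm.n_variants):
        lab = _classify(gm.dosages[:, j], 0.05, 0.90)
        counts[lab] = counts.get(lab, 0) + 1
    assert counts == {
        "low_maf": 13, "low_callrate": 21, "with_missing": 16, "complete": 10,
    }


def test_fixture_all_complete_passes_untouched():
    from famgwas.qc import filter_variants

    profile = simdata.QCFixtureProfile(25, 0, 0, 0, 25, seed=1)
    gm = simdata.make_qc_fixture(profile, n_samples=50)
    out, report = filter_variants(gm)
    assert out.n_variants == 25
    assert report.n_removed_maf == report.n_removed_callrate == 0


def test_fixture_rejects_inconsistent_profile():
    with pytest.raises(ValueError, match="n_variants_total"):
        simdata.QCFixtureProfile(10, 5, 5, 5, 5)
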