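import numpy as np
import pytest

from famgwas import simdata


@pytest.fixture(scope="session")
def study_pedigree():
    """The study design: 7 families, 13 parents, 105 offspring."""
    return simdata.simulate_pedigree(**simdata.study_pedigree_profile(), seed=11)


@pytest.fixture(scope="session")
def study_cohort(study_pedigree):
    """Genotypes (800 variants, common MAF) + offspring phenotype with a QTL."""
    gm = simdata.simulate_genotypes(
        study_pedigree,
        n_variants=800,
        maf_sampler=lambda rng, k: rng.uniform(0.2, 0.5, k),
        seed=12,
    )
    qtl = gm.variant_ids[40]
    spec = simdata.TraitModelSpec(
        intercept=10.0, beta={qtl: 2.0}, var_family=2.0, var_resid=1.0,
        name="trait",
    )
    phenos = simdata.simulate_phenotypes(gm, study_pedigree, spec, seed=13)
    return {"gm": gm, "ped": study_pedigree, "phenos": phenos, "qtl": qtl,
            "spec": spec}


@pytest.fixture(scope="session")
def offspring_data(study_cohort):
    """Offspring-only dosage matrix aligned with the phenotype table."""
    ph = study_cohort["phenos"]
    gm = study_cohort["gm"].subset_samples(ph["sample_id"].tolist())
    return {
        "gm": gm,
        "y": ph["trait"].to_numpy(),
        "fam": ph["family_id"].to_numpy(),
        "qtl": study_cohort["qtl"],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
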