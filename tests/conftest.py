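import numpy as np
import pandas as pd
import pytest

import kinherit as kh


@pytest.fixture(scope="session")
def small_study():
    """10 families (140 people), 1,000 SNPs, moderately heritable trait."""
    cfg = kh.SimulationConfig(n_families=10, n_snps=1000, true_h2=0.5, seed=7)
    ped, geno, pheno = kh.simulate_study(cfg)
    return cfg, ped, geno, pheno


@pytest.fixture(scope="session")
def small_kinship(small_study):
    _, ped, _, _ = small_study
    return kh.pedigree_kinship(ped)


@pytest.fixture()
def trio_pedigree():
    return kh.Pedigree(pd.DataFrame({
        "family_id": ["1"] * 3,
        "individual_id": ["F", "M", "C"],
        "father_id": [None, None, "F"],
        "mother_id": [None, None, "M"],
        "sex": ["M", "F", "F"],
    }))


def make_pedigree(rows):
    """rows: (fam, id, fa, mo, sex) tuples."""
    return kh.Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id",
                       "mother_id", "sex"]))
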