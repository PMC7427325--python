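import numpy as np
import pandas as pd
import pytest

import cryptevolve as ce


def make_matrix(var, dp, crypts=None, vclass="SNV", sex="female", chrom="1"):
    """Small GenotypeMatrix from literal count arrays."""
    var = np.atleast_2d(var)
    dp = np.atleast_2d(dp)
    n_sites, n_crypts = var.shape
    crypts = crypts or [f"c{j + 1}" for j in range(n_crypts)]
    vclass = [vclass] * n_sites if isinstance(vclass, str) else vclass
    chrom = [chrom] * n_sites if isinstance(chrom, str) else chrom
    sites = pd.DataFrame({
        "site_id": [f"s{i + 1}" for i in range(n_sites)],
        "chrom": chrom, "pos": np.arange(100, 100 + n_sites * 10, 10),
        "ref": "C", "alt": "T", "vclass": vclass,
    })
    return ce.GenotypeMatrix("P1", sites, var, dp, crypts, sex)


@pytest.fixture(scope="session")
def small_cohort():
    """Site-level cohort small enough for full-pipeline tests."""
    cfg = ce.CohortConfig(
        n_patients_case=2, n_patients_control=2, biopsies_per_patient=2,
        crypts_per_biopsy=3, age_sub_rate=1.5, disease_sub_rate=2.0,
        age_indel_rate=0.3, disease_indel_rate=0.3,
        patient_sd_case=5, patient_sd_control=5,
        biopsy_sd_case=5, biopsy_sd_control=5,
        indel_patient_sd_case=2, indel_patient_sd_control=2,
        indel_biopsy_sd_case=2, indel_biopsy_sd_control=2,
        n_germline=30, n_artifact=10, seed=7,
    )
    matrices, meta, truth = ce.simulate_cohort(cfg)
    return cfg, matrices, meta, truth


@pytest.fixture(scope="session")
def paper_cohort():
    """Burden-level cohort at the default (study-scale) rates."""
    cfg = ce.CohortConfig(seed=5)
    _, meta, truth = ce.simulate_cohort(cfg, genotypes=False)
    return cfg, meta, truth
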