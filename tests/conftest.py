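import numpy as np
import pandas as pd
import pytest

from driverscape.io_filtering import ArmCallTable, GeneSampleMatrix

ALL_COHORTS = ("COAD", "BRCA", "LUAD", "UCEC")


def gene_matrix(values, entrez=None, samples=None, hugo=None) -> GeneSampleMatrix:
    """Small GeneSampleMatrix from a nested list / array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    entrez = list(entrez) if entrez is not None else list(range(1, n_genes + 1))
    samples = (list(samples) if samples is not None
               else [f"TCGA-AA-{i:04d}-01A" for i in range(1, n_samples + 1)])
    hugo = list(hugo) if hugo is not None else [f"G{e}" for e in entrez]
    idx = pd.Index(entrez, name="Entrez_Gene_Id")
    return GeneSampleMatrix(pd.DataFrame(values, index=idx, columns=samples),
                            pd.Series(hugo, index=idx))


def arm_table(values, samples=None, arms=None) -> ArmCallTable:
    values = np.asarray(values, dtype=float)
    n_samples, n_arms = values.shape
    samples = (list(samples) if samples is not None
               else [f"TCGA-AA-{i:04d}-01A" for i in range(1, n_samples + 1)])
    arms = list(arms) if arms is not None else [f"{i}p" for i in range(1, n_arms + 1)]
    return ArmCallTable(pd.DataFrame(values, index=samples, columns=arms))


@pytest.fixture(scope="session")
def null_dataset():
    """One background-only synthetic dataset (no planted drivers)."""
    from driverscape.synthetic_data import TruthConfig, generate
    return generate(TruthConfig(seed=101))


@pytest.fixture(scope="session")
def planted_dataset():
    """Dataset with a pancancer oncogene/suppressor and one arm gain."""
    from driverscape.synthetic_data import TruthConfig, generate
    config = TruthConfig(
        seed=202,
        # CNA frequency kept below 0.5 so each gene's cross-patient median
        # stays at the unaltered baseline that relative encoding assumes
        planted_oncogenes={c: [("ONCO1", 0.15, 0.3)] for c in ALL_COHORTS},
        planted_suppressors={c: [("SUPP1", 0.15, 0.3)] for c in ALL_COHORTS},
        planted_arm_events={"LUAD": [("3p", 1, 0.4)]},
        planted_chromosome_events={"UCEC": [("7", 1, 0.4)]},
        expression_concordance=1.0,
    )
    return generate(config)
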