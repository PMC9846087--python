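import numpy as np
import pandas as pd
import pytest

from sexdiffscreen import (
    ScSimConfig,
    normalize_counts,
    simulate_sc_dataset,
)
from sexdiffscreen.gwas_io import CANONICAL_COLUMNS


def make_gwas_frame(rows):
    """Build a canonical summary-statistic frame from compact row tuples
    (snp_id, chrom, pos, ea, oa, eaf, beta, se, p)."""
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS[:9]))
    df["n_cases"] = pd.array([None] * len(df), dtype="Int64")
    df["n_controls"] = pd.array([None] * len(df), dtype="Int64")
    df["pos"] = df["pos"].astype("Int64")
    df["chrom"] = df["chrom"].astype("string")
    return df


@pytest.fixture
def three_snp_frame():
    return make_gwas_frame(
        [
            ("rs1", "2", 1_000_000, "A", "G", 0.30, 0.20, 0.10, 0.046),
            ("rs2", "2", 1_200_000, "T", "C", 0.10, -0.05, 0.08, 0.53),
            ("rs3", "3", 900_000, "A", "C", 0.45, 0.01, 0.05, 0.84),
        ]
    )


@pytest.fixture(scope="session")
def small_sc_config():
    """A scaled-down four-group single-cell design for fast tests."""
    return ScSimConfig(
        n_per_group={
            "case_female": 4,
            "case_male": 4,
            "control_female": 4,
            "control_male": 4,
        },
        cell_types=("cardiomyocyte", "vsmc", "fibroblast"),
        base_composition=(0.5, 0.1, 0.4),
        cells_per_sample=150,
        n_genes=10,
    )


@pytest.fixture(scope="session")
def small_sc_dataset(small_sc_config):
    sim = simulate_sc_dataset(small_sc_config, seed=7)
    normalize_counts(sim.dataset)
    return sim
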