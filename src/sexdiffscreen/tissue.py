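"""Per-tissue sex differential expression of a single gene on bulk TPM.

For each tissue with at least two samples per sex, expression of the target
gene (optionally log2(TPM+1)-transformed) is compared between females and
males with a one-way ANOVA F test — for two groups this is exactly the
pooled-variance two-sample t-test (F = t^2).  Significance is reported both
nominally and under a per-tissue Bonferroni bound alpha / n_tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, LookupError_

SEXES = ("female", "male")


@dataclass
class TissueExpressionMatrix:
    """Gene x sample TPM matrix with per-sample tissue and sex labels.

    ``tpm`` is indexed by gene with sample-id columns; ``samples`` is indexed
    by sample id with ``tissue`` and ``sex`` columns covering every matrix
    column.
    """

    tpm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tpm.columns.has_duplicates:
            raise DataError("duplicate sample ids in TPM matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise DataError("TPM values must be >= 0")
        missing = self.tpm.columns.difference(self.samples.index)
        if len(missing):
            raise DataError(f"samples lacking metadata: {sorted(missing)[:5]} ...")
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise DataError(f"unknown sex label(s): {sorted(bad_sex)}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())


def read_tpm_matrix(
    matrix_path: str | Path, attributes_path: str | Path
) -> TissueExpressionMatrix:
    """Read a TPM matrix (plain TSV, or GCT with its 2-line preamble) plus a
    sample-attribute TSV with columns sample_id, tissue, sex."""
    with open(matrix_path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):  # GCT: version line, dims line, then table
        tpm = pd.read_csv(matrix_path, sep="\t", skiprows=2, index_col=0)
        if "Description" in tpm.columns:
            tpm = tpm.drop(columns="Description")
    else:
        tpm = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(attributes_path, sep="\t", index_col="sample_id")
    return TissueExpressionMatrix(tpm=tpm, samples=samples)


def write_tpm_matrix(
    mat: TissueExpressionMatrix, matrix_path: str | Path, attributes_path: str | Path
) -> None:
    mat.tpm.to_csv(matrix_path, sep="\t", index_label="gene")
    mat.samples.to_csv(attributes_path, sep="\t", index_label="sample_id")


def _two_group_anova(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    """(F, p) for a two-group one-way ANOVA; degenerate zero-variance,
    zero-difference inputs give F = 0, p = 1 rather than NaN."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    if welch:
        t = stats.ttest_ind(a, b, equal_var=False)
    else:
        t = stats.ttest_ind(a, b, equal_var=True)
    return float(t.statistic**2), float(t.pvalue)


def sex_anova_per_tissue(
    matrix: TissueExpressionMatrix,
    gene: str,
    transform: str = "log2p1",
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Sex differential expression of ``gene`` in every tissue.

    Returns one row per tissue: sample counts and group means per sex, the
    F statistic and its p-value, a nominal flag (p <= alpha) and an adjusted
    flag (p <= alpha / n_tested_tissues).  Tissues with fewer than two
    samples of either sex are listed with ``tested = False`` and NaN
    statistics rather than silently dropped.
    """
    if transform not in {"log2p1", "none"}:
        raise ConfigurationError(f"unknown transform {transform!r}")
    if gene not in matrix.tpm.index:
        raise LookupError_(f"gene {gene!r} absent from the TPM matrix")
    values = matrix.tpm.loc[gene].astype(float)
    if transform == "log2p1":
        values = np.log2(values + 1.0)

    rows = []
    for tissue in matrix.tissues:
        ids = matrix.samples.index[matrix.samples["tissue"] == tissue]
        ids = ids.intersection(values.index)
        sex = matrix.samples.loc[ids, "sex"]
        grp = {s: values[ids[(sex == s).to_numpy()]].to_numpy() for s in SEXES}
        testable = all(len(grp[s]) >= 2 for s in SEXES)
        f_stat, p = (np.nan, np.nan)
        if testable:
            f_stat, p = _two_group_anova(grp["female"], grp["male"], welch=welch)
        rows.append(
            {
                "tissue": tissue,
                "n_female": len(grp["female"]),
                "n_male": len(grp["male"]),
                "mean_female": float(np.mean(grp["female"])) if len(grp["female"]) else np.nan,
                "mean_male": float(np.mean(grp["male"])) if len(grp["male"]) else np.nan,
                "F": f_stat,
                "p": p,
                "tested": testable,
            }
        )
    out = pd.DataFrame(rows)
    n_tested = int(out["tested"].sum())
    threshold = alpha / n_tested if n_tested else np.nan
    out["significant_nominal"] = out["p"] <= alpha
    out["significant_adjusted"] = out["p"] <= threshold
    out.attrs["threshold"] = threshold
    out.attrs["n_tested"] = n_tested
    out.attrs["gene"] = gene
    out.attrs["transform"] = transform
    return out
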