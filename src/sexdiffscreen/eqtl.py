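"""Multi-tissue cis-eQTL annotation of screen hits.

Consumes GTEx-style per-tissue eQTL exports (tissue, sample size, signed
normalized effect size, nominal p, cross-tissue meta-analysis m-value) for
one SNP x gene pair, orients the effect onto the trait risk allele, applies
a per-tissue Bonferroni bound, and flags cross-tissue consistency by the
m-value rule (posterior probability that the effect exists in the tissue
strictly above the cutoff, conventionally 0.5).

The m-value is consumed as published, never recomputed here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

EQTL_COLUMNS = ("gene", "snp_id", "tissue", "sample_size", "nes", "p_nominal", "m_value")

_READ_ALIASES = {
    "snp": "snp_id", "n": "sample_size", "p": "p_nominal", "mvalue": "m_value",
}


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """Read a tissue eQTL TSV with columns
    gene, snp, tissue, n, nes, p, mvalue (or their canonical names)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_READ_ALIASES)
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: eQTL table missing column(s) {missing}")
    validate_eqtl_table(df)
    return df.loc[:, list(EQTL_COLUMNS)]


def write_eqtl_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_eqtl_table(df: pd.DataFrame) -> None:
    bad = []
    if (df["sample_size"] < 1).any():
        bad.append("sample_size must be >= 1")
    if ((df["p_nominal"] <= 0) | (df["p_nominal"] > 1)).any():
        bad.append("p_nominal must be in (0, 1]")
    if ((df["m_value"] < 0) | (df["m_value"] > 1)).any():
        bad.append("m_value must be in [0, 1]")
    if bad:
        raise ValidationError("; ".join(bad))


def consistency_flag(m_value: float, cutoff: float = 0.5) -> bool:
    """True when the posterior probability of a tissue effect strictly
    exceeds the cutoff."""
    if not 0 <= m_value <= 1:
        raise ValidationError(f"m_value must be in [0, 1] (got {m_value})")
    return m_value > cutoff


def annotate_tissues(
    records: pd.DataFrame,
    risk_allele_is_effect_allele: bool = True,
    alpha: float = 0.05,
    m_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Annotate one SNP x gene's per-tissue eQTL records.

    The NES sign is flipped when the trait risk allele is not the eQTL
    effect allele, so ``direction`` always describes the risk allele's
    association with expression.  ``significant`` applies the per-tissue
    Bonferroni bound p_nominal <= alpha / n_tissues (inclusive, matching
    the convention of reporting "p <= 0.05/k"); ``consistent`` applies the
    strict m-value rule.  Output is sorted by nominal p ascending.
    """
    validate_eqtl_table(records)
    if records["snp_id"].nunique() > 1 or records["gene"].nunique() > 1:
        raise DataError(
            "annotate_tissues expects records for a single SNP x gene pair; got "
            f"snps={sorted(records['snp_id'].unique())} genes={sorted(records['gene'].unique())}"
        )
    n_tissues = len(records)
    threshold = alpha / n_tissues
    out = records.copy()
    nes = out["nes"].astype(float)
    if not risk_allele_is_effect_allele:
        nes = -nes
    out["nes_risk"] = nes
    out["direction"] = np.where(nes >= 0, "positive", "negative")
    out["significant"] = out["p_nominal"] <= threshold
    out["consistent"] = out["m_value"] > m_cutoff
    out.attrs["threshold"] = threshold
    out.attrs["n_tissues"] = n_tissues
    return out.sort_values(["p_nominal", "tissue"], kind="mergesort").reset_index(
        drop=True
    )


def summarize_annotation(annotated: pd.DataFrame) -> dict:
    """JSON-ready digest: significant tissues, consistent tissues, and the
    direction split of the risk-allele effect."""
    return {
        "n_tissues": int(len(annotated)),
        "threshold": float(annotated.attrs.get("threshold", np.nan)),
        "significant_tissues": annotated.loc[
            annotated["significant"], "tissue"
        ].tolist(),
        "consistent_tissues": annotated.loc[annotated["consistent"], "tissue"].tolist(),
        "n_negative": int((annotated["direction"] == "negative").sum()),
        "n_positive": int((annotated["direction"] == "positive").sum()),
    }
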