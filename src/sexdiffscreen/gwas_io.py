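"""Reading, validation and allele harmonization of sex-stratified GWAS
summary statistics.

The in-memory currency of this module is a :class:`pandas.DataFrame` with a
fixed canonical schema (:data:`CANONICAL_COLUMNS`); :class:`GwasRecord` is
the validated single-row view.  Files are tab-delimited summary-statistic
tables in the style distributed by GWAS repositories (GRASP, GWAS Catalog),
with a small "dialect" mapping translating arbitrary column headers onto the
canonical names.  Coordinates are 1-based throughout and genomic windows are
closed intervals, matching summary-statistic convention.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DuplicateSnpError,
    IncompatibleVariantError,
    LookupError_,
    ValidationError,
)

#: Canonical column order for summary-statistic frames.
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n_cases",
    "n_controls",
)

#: Columns that must be present (directly or via the dialect) in any file.
REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "p")

#: Default file-header names, one per canonical column.
DEFAULT_HEADER = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
}

#: Strand-ambiguous allele pairs (identical to their reverse complement).
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary from one sex stratum."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        problems = _field_problems(
            eaf=self.eaf, beta=self.beta, se=self.se, p=self.p, pos=self.pos,
            effect_allele=self.effect_allele, other_allele=self.other_allele,
        )
        if problems:
            raise ValidationError(f"invalid record {self.snp_id!r}: {'; '.join(problems)}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from canonical column names to file header names.

    Only entries that differ from :data:`DEFAULT_HEADER` need to be given.
    """

    header: Mapping[str, str] = field(default_factory=dict)

    def resolve(self) -> dict[str, str]:
        unknown = set(self.header) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"dialect maps unknown canonical columns: {sorted(unknown)}"
            )
        merged = dict(DEFAULT_HEADER)
        merged.update(self.header)
        return merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnDialect":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"dialect file {path} must hold a mapping")
        return cls(header=payload)


def _field_problems(*, eaf, beta, se, p, pos, effect_allele, other_allele) -> list[str]:
    problems = []
    if not math.isfinite(beta):
        problems.append(f"beta not finite ({beta})")
    if not (math.isfinite(se) and se > 0):
        problems.append(f"se must be > 0 (got {se})")
    if not (math.isfinite(p) and 0 < p <= 1):
        problems.append(f"p must be in (0, 1] (got {p})")
    if not (isinstance(eaf, float) and math.isnan(eaf)) and not (0 <= eaf <= 1):
        problems.append(f"eaf must be in [0, 1] (got {eaf})")
    if pos is not None and not (isinstance(pos, float) and math.isnan(pos)) and pos < 1:
        problems.append(f"pos must be >= 1 (got {pos})")
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if ea == oa:
        problems.append(f"effect and other allele identical ({ea})")
    return problems


def _validate_frame(df: pd.DataFrame, source: str) -> None:
    """Raise :class:`ValidationError` naming every malformed row."""
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    p = df["p"].to_numpy(dtype=float)
    eaf = df["eaf"].to_numpy(dtype=float)
    pos = df["pos"].to_numpy(dtype=float, na_value=np.nan)
    suspect = ~(
        np.isfinite(beta)
        & np.isfinite(se) & (se > 0)
        & np.isfinite(p) & (p > 0) & (p <= 1)
        & (np.isnan(eaf) | ((eaf >= 0) & (eaf <= 1)))
        & (np.isnan(pos) | (pos >= 1))
        & (df["effect_allele"].to_numpy() != df["other_allele"].to_numpy())
    )
    if suspect.any():
        bad: list[str] = []
        for idx in np.flatnonzero(suspect):
            row = df.iloc[idx]
            problems = _field_problems(
                eaf=float(eaf[idx]), beta=float(beta[idx]), se=float(se[idx]),
                p=float(p[idx]), pos=None if np.isnan(pos[idx]) else float(pos[idx]),
                effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            )
            bad.append(f"row {df.index[idx]} ({row['snp_id']}): {'; '.join(problems)}")
        raise ValidationError(
            f"{source}: {len(bad)} malformed row(s):\n" + "\n".join(bad)
        )
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise DuplicateSnpError(f"{source}: duplicated snp_id: {sorted(set(dup))}")


def read_gwas_summary(
    path: str | Path,
    dialect: ColumnDialect | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistic table into the canonical frame.

    gzip-compressed files are handled transparently.  Rows are returned in
    file order; every row must satisfy the record invariants, otherwise a
    :class:`ValidationError` naming each offending row is raised.
    """
    if dialect is None:
        dialect = ColumnDialect()
    elif not isinstance(dialect, ColumnDialect):
        dialect = ColumnDialect(header=dict(dialect))
    header = dialect.resolve()

    raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [
        header[c] for c in REQUIRED_COLUMNS if header[c] not in raw.columns
    ]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) missing: {missing} "
            f"(headers present: {list(raw.columns)})"
        )

    out = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        col = header[canon]
        out[canon] = raw[col] if col in raw.columns else pd.NA
    out["snp_id"] = out["snp_id"].astype(str)
    out["chrom"] = out["chrom"].astype("string")
    for allele in ("effect_allele", "other_allele"):
        out[allele] = out[allele].astype(str).str.upper()
    for num, dtype in (
        ("pos", "Int64"), ("n_cases", "Int64"), ("n_controls", "Int64"),
    ):
        out[num] = pd.to_numeric(out[num], errors="coerce").astype(dtype)
    for num in ("eaf", "beta", "se", "p"):
        out[num] = pd.to_numeric(out[num], errors="coerce")

    _validate_frame(out, source=str(path))
    return out.reset_index(drop=True)


def write_gwas_summary(
    df: pd.DataFrame,
    path: str | Path,
    dialect: ColumnDialect | None = None,
) -> None:
    """Write a canonical frame back to the tab-delimited file dialect."""
    header = (dialect or ColumnDialect()).resolve()
    out = df.loc[:, list(CANONICAL_COLUMNS)].rename(columns=header)
    out.to_csv(path, sep="\t", index=False)


def records(df: pd.DataFrame) -> Iterable[GwasRecord]:
    """Iterate a canonical frame as validated :class:`GwasRecord` objects."""
    for _, row in df.iterrows():
        yield GwasRecord(
            snp_id=row["snp_id"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]) if pd.notna(row["pos"]) else 1,
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]) if pd.notna(row["eaf"]) else float("nan"),
            beta=float(row["beta"]),
            se=float(row["se"]),
            p=float(row["p"]),
            n_cases=int(row["n_cases"]) if pd.notna(row["n_cases"]) else None,
            n_controls=int(row["n_controls"]) if pd.notna(row["n_controls"]) else None,
        )


def frame_from_records(recs: Sequence[GwasRecord]) -> pd.DataFrame:
    """Build a canonical frame from validated records (inverse of ``records``)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in recs], columns=CANONICAL_COLUMNS)
    df["pos"] = df["pos"].astype("Int64")
    df["n_cases"] = df["n_cases"].astype("Int64")
    df["n_controls"] = df["n_controls"].astype("Int64")
    df["chrom"] = df["chrom"].astype("string")
    return df


# ---------------------------------------------------------------------------
# Candidate SNP panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpPanel:
    """An ordered panel of candidate SNP ids, optionally annotated with the
    mapped gene and source trait."""

    snp_ids: tuple[str, ...]
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValidationError("SNP panel is empty")
        seen = pd.Index(self.snp_ids)
        if seen.has_duplicates:
            dupes = sorted(set(seen[seen.duplicated()]))
            raise DuplicateSnpError(f"panel contains duplicate snp_id: {dupes}")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self):
        return iter(self.snp_ids)


def read_snp_panel(path: str | Path) -> SnpPanel:
    """Read a panel file: either one SNP id per line, or a TSV whose first
    column is the SNP id with optional ``gene`` / ``trait`` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] == 1 and df.columns[0] not in {"snp_id", "SNP", "snp"}:
        # headerless one-column list
        ids = [df.columns[0]] + df.iloc[:, 0].tolist()
        return SnpPanel(snp_ids=tuple(ids))
    ids = tuple(df.iloc[:, 0].astype(str))
    annotations = df if df.shape[1] > 1 else None
    return SnpPanel(snp_ids=ids, annotations=annotations)


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    if panel.annotations is not None:
        panel.annotations.to_csv(path, sep="\t", index=False)
    else:
        pd.Series(panel.snp_ids, name="snp_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sex-pair harmonization
# ---------------------------------------------------------------------------

@dataclass
class PairedSexGwas:
    """Per-SNP aligned female/male summary statistics on a shared effect
    allele.

    ``pairs`` holds one row per SNP with ``_f``/``_m`` suffixed statistic
    columns; ``dropped_female``/``dropped_male`` list SNP ids present in only
    one stratum; ``ambiguous`` lists strand-ambiguous (A/T, C/G) SNPs kept or
    dropped per the harmonization policy.
    """

    pairs: pd.DataFrame
    dropped_female: tuple[str, ...] = ()
    dropped_male: tuple[str, ...] = ()
    ambiguous: tuple[str, ...] = ()
    n_flipped: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def stratum(self, sex: str) -> pd.DataFrame:
        """Project one sex back to a canonical single-stratum frame."""
        if sex not in {"female", "male"}:
            raise LookupError_(f"unknown stratum {sex!r}")
        suffix = "_f" if sex == "female" else "_m"
        out = self.pairs[
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
        ].copy()
        for col in ("eaf", "beta", "se", "p", "n_cases", "n_controls"):
            out[col] = self.pairs[f"{col}{suffix}"]
        return out


def harmonize_pair(
    female: pd.DataFrame,
    male: pd.DataFrame,
    ambiguous_policy: str = "keep",
) -> PairedSexGwas:
    """Pair female and male records on a shared effect allele.

    If the male record's alleles are swapped relative to the female's, the
    male beta is negated, its EAF becomes ``1 - eaf`` and the alleles are
    swapped, so that both betas afterwards measure the same allele's effect.
    Allele sets matching neither directly nor after a swap raise
    :class:`IncompatibleVariantError`.  Strand-ambiguous pairs (A/T, C/G) are
    indistinguishable from an opposite-strand report; the default policy
    keeps them under a same-strand assumption (both strata here typically
    derive from a single cohort), ``ambiguous_policy="drop"`` removes them.
    """
    if ambiguous_policy not in {"keep", "drop"}:
        raise ConfigurationError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    _validate_frame(female, "female stratum")
    _validate_frame(male, "male stratum")

    f = female.set_index("snp_id", drop=False)
    m = male.set_index("snp_id", drop=False)
    shared = f.index.intersection(m.index)
    dropped_female = tuple(f.index.difference(m.index))
    dropped_male = tuple(m.index.difference(f.index))

    fs = f.loc[shared]
    ms = m.loc[shared].copy()

    direct = (ms["effect_allele"] == fs["effect_allele"]) & (
        ms["other_allele"] == fs["other_allele"]
    )
    swapped = (ms["effect_allele"] == fs["other_allele"]) & (
        ms["other_allele"] == fs["effect_allele"]
    )
    incompatible = ~(direct | swapped)
    if incompatible.any():
        bad = sorted(shared[incompatible])
        raise IncompatibleVariantError(
            f"allele sets irreconcilable between strata for: {bad}"
        )

    flip = swapped.to_numpy()
    ms.loc[flip, "beta"] = -ms.loc[flip, "beta"]
    ms.loc[flip, "eaf"] = 1.0 - ms.loc[flip, "eaf"]
    ms.loc[flip, ["effect_allele", "other_allele"]] = ms.loc[
        flip, ["other_allele", "effect_allele"]
    ].to_numpy()

    is_ambiguous = [
        frozenset((ea, oa)) in AMBIGUOUS_PAIRS
        for ea, oa in zip(fs["effect_allele"], fs["other_allele"])
    ]
    is_ambiguous = np.asarray(is_ambiguous)
    ambiguous_ids = tuple(shared[is_ambiguous])

    pairs = fs[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    for col in ("eaf", "beta", "se", "p", "n_cases", "n_controls"):
        pairs[f"{col}_f"] = fs[col]
        pairs[f"{col}_m"] = ms[col]
    pairs["allele_flipped"] = flip
    pairs["strand_ambiguous"] = is_ambiguous
    if ambiguous_policy == "drop":
        pairs = pairs.loc[~is_ambiguous]
    pairs = pairs.reset_index(drop=True)

    return PairedSexGwas(
        pairs=pairs,
        dropped_female=dropped_female,
        dropped_male=dropped_male,
        ambiguous=ambiguous_ids,
        n_flipped=int(flip.sum()),
    )


# ---------------------------------------------------------------------------
# Genomic windows
# ---------------------------------------------------------------------------

def extract_window(
    df: pd.DataFrame,
    center: str,
    width: float = 1_000_000,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Records on the center SNP's chromosome within ``width/2`` base pairs
    of it (closed interval, 1-based) whose minor-allele frequency strictly
    exceeds ``maf_min``.

    The MAF filter is a strict inequality (common variants only); the center
    SNP itself is subject to the same filter.
    """
    if width <= 0:
        raise ConfigurationError(f"window width must be > 0 (got {width})")
    hit = df.loc[df["snp_id"] == center]
    if hit.empty:
        raise LookupError_(f"center SNP {center!r} not present")
    row = hit.iloc[0]
    if pd.isna(row["pos"]) or pd.isna(row["chrom"]):
        raise LookupError_(f"center SNP {center!r} lacks chrom/pos")
    lo = float(row["pos"]) - width / 2
    hi = float(row["pos"]) + width / 2
    pos = df["pos"].astype(float)
    maf = np.minimum(df["eaf"].astype(float), 1.0 - df["eaf"].astype(float))
    keep = (
        (df["chrom"] == row["chrom"]) & (pos >= lo) & (pos <= hi) & (maf > maf_min)
    )
    return df.loc[keep.fillna(False)].reset_index(drop=True)
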