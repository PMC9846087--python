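"""Dual-level single-cell differential expression of one gene across a
sex x disease four-group design.

Two complementary procedures operate on a cell x gene count matrix with
per-cell (cell type, sample, sex, disease) labels:

* **Sample level** — cells are rolled up to one row per sample x cell type
  (cell count, share of the sample, count/share of expressing cells, median
  log2(normalized expression + 1)); each roll-up metric is then compared
  across the four sex x disease groups with all pairwise Tukey-Kramer
  contrasts from a one-way fit.  This treats the sample, not the cell, as
  the unit of replication (a pseudobulk design).
* **Cell level** — all cells of one type are pooled per group and compared
  pairwise with the two-sided Wilcoxon rank-sum test on log-normalized
  values, reporting the average log2 fold change and the percent of cells
  expressing the gene, under a Bonferroni bound over all
  (expressed cell type) x (group pair) comparisons.

Counts are normalized Seurat-style: per cell, ln(1 + count / total * scale)
with scale 10,000.  A cell "expresses" the gene iff its normalized value is
positive, i.e. iff its raw count is nonzero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateStatisticsError,
    LookupError_,
)

OBS_COLUMNS = ("cell_type", "sample_id", "sex", "disease")
DISEASE_LEVELS = ("case", "control")
SEX_LEVELS = ("female", "male")
#: The four sex x disease groups, in reporting order.
GROUPS = ("case_female", "case_male", "control_female", "control_male")
LOGNORM_LAYER = "lognorm"
DEFAULT_SCALE = 10_000.0
LN2 = float(np.log(2.0))


def stars(p: float) -> str:
    """Figure-legend significance stars: * <=0.05 ... **** <=0.0001."""
    for cutoff, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p <= cutoff:
            return mark
    return "ns"


@dataclass
class SingleCellDataset:
    """A cell x gene matrix with the four-group design labels.

    Wraps an :class:`anndata.AnnData` whose ``obs`` carries ``cell_type``,
    ``sample_id``, ``sex`` and ``disease``; a combined ``group`` column
    (``disease_sex``) is derived on construction.  ``X`` holds raw counts;
    log-normalized values live in ``layers["lognorm"]`` after
    :func:`normalize_counts`.
    """

    adata: ad.AnnData

    def __post_init__(self) -> None:
        obs = self.adata.obs
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise DataError(f"cell metadata lacks column(s): {missing}")
        for col in OBS_COLUMNS:
            if obs[col].isna().any():
                raise DataError(f"cells with missing {col!r} label")
        bad_sex = set(obs["sex"]) - set(SEX_LEVELS)
        bad_dis = set(obs["disease"]) - set(DISEASE_LEVELS)
        if bad_sex or bad_dis:
            raise DataError(
                f"unknown labels: sex={sorted(bad_sex)} disease={sorted(bad_dis)}"
            )
        X = self.adata.X
        mn = X.min() if not sparse.issparse(X) else X.data.min(initial=0)
        if mn < 0:
            raise DataError("counts must be nonnegative")
        obs["group"] = (
            obs["disease"].astype(str) + "_" + obs["sex"].astype(str)
        )
        nested = obs.groupby("sample_id", observed=True)["group"].nunique()
        if (nested > 1).any():
            bad = nested.index[nested > 1].tolist()
            raise DataError(f"samples assigned to more than one group: {bad}")

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    def lognorm(self) -> np.ndarray | sparse.spmatrix:
        if LOGNORM_LAYER not in self.adata.layers:
            raise DataError("dataset is not normalized; call normalize_counts first")
        return self.adata.layers[LOGNORM_LAYER]

    def gene_values(self, gene: str, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-cell log-normalized values of one gene (dense 1-D)."""
        if gene not in self.adata.var_names:
            raise LookupError_(f"gene {gene!r} absent from the matrix")
        j = self.adata.var_names.get_loc(gene)
        col = self.lognorm()[:, j]
        vec = np.asarray(col.todense()).ravel() if sparse.issparse(col) else np.asarray(col).ravel()
        return vec if mask is None else vec[mask]


def load_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    genes_path: str | Path | None = None,
) -> SingleCellDataset:
    """Load counts (Matrix-Market cell x gene, or dense TSV with cell rows
    and gene columns) plus a cell-metadata TSV
    (cell_id, cell_type, sample_id, sex, disease)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("cell_id")
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        X = sparse.csr_matrix(spio.mmread(counts_path))
        if genes_path is None:
            raise ConfigurationError("MTX input requires a genes file")
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        if X.shape[0] != len(meta) or X.shape[1] != len(genes):
            raise DataError(
                f"matrix shape {X.shape} does not match "
                f"{len(meta)} cells x {len(genes)} genes"
            )
        adata = ad.AnnData(
            X=X, obs=meta, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
        )
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        dense = dense.loc[meta.index]
        adata = ad.AnnData(
            X=sparse.csr_matrix(dense.to_numpy(dtype=float)),
            obs=meta,
            var=pd.DataFrame(index=dense.columns.rename("gene")),
        )
    return SingleCellDataset(adata=adata)


def save_dataset(
    ds: SingleCellDataset,
    counts_path: str | Path,
    metadata_path: str | Path,
    genes_path: str | Path,
) -> None:
    """Write counts as Matrix-Market plus gene and cell-metadata TSVs."""
    X = ds.adata.X
    spio.mmwrite(str(counts_path), sparse.coo_matrix(X))
    pd.Series(ds.adata.var_names).to_csv(genes_path, sep="\t", index=False, header=False)
    ds.adata.obs.loc[:, list(OBS_COLUMNS)].to_csv(
        metadata_path, sep="\t", index_label="cell_id"
    )


def normalize_counts(ds: SingleCellDataset, scale: float = DEFAULT_SCALE) -> SingleCellDataset:
    """Library-size log normalization: per cell, ln(1 + count/total * scale).

    Cells with zero total counts are dropped with a warning.  Returns the
    dataset with the ``lognorm`` layer set (in place).
    """
    if scale <= 0:
        raise ConfigurationError(f"scale must be > 0 (got {scale})")
    X = sparse.csr_matrix(ds.adata.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        n0 = int((totals == 0).sum())
        warnings.warn(f"dropping {n0} cell(s) with zero total counts", stacklevel=2)
        ds.adata = ds.adata[totals > 0].copy()
        X = sparse.csr_matrix(ds.adata.X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
    norm = X.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    ds.adata.layers[LOGNORM_LAYER] = norm
    return ds


# ---------------------------------------------------------------------------
# Sample-level roll-up
# ---------------------------------------------------------------------------

def summarize_samples(
    ds: SingleCellDataset, gene: str, min_cells: int = 100, exclude_low: bool = False
) -> pd.DataFrame:
    """One row per (sample, cell type) with at least one cell.

    Columns: n_cells, pct_of_sample (against the sample's total over all
    cell types), n_expressing / pct_expressing under the positive-normalized
    rule, and median_log2 — the median over cells of
    log2(normalized expression + 1), obtained by rescaling the natural-log
    normalized values (both scales are monotone, so the median transports).
    Sample x cell-type strata below ``min_cells`` cells are flagged
    (``below_min_cells``) and, when ``exclude_low``, dropped.
    """
    vec = ds.gene_values(gene)
    obs = ds.adata.obs
    rows = []
    sample_totals = obs.groupby("sample_id", observed=True).size()
    grouped = obs.groupby(["sample_id", "cell_type"], observed=True).indices
    for (sample_id, cell_type), idx in grouped.items():
        x = vec[idx]
        n = len(idx)
        n_exp = int((x > 0).sum())
        rows.append(
            {
                "sample_id": sample_id,
                "cell_type": cell_type,
                "group": obs["group"].iloc[idx[0]],
                "sex": obs["sex"].iloc[idx[0]],
                "disease": obs["disease"].iloc[idx[0]],
                "n_cells": n,
                "pct_of_sample": n / sample_totals[sample_id],
                "n_expressing": n_exp,
                "pct_expressing": n_exp / n,
                "median_log2": float(np.median(x)) / LN2,
                "below_min_cells": n < min_cells,
            }
        )
    out = pd.DataFrame(rows).sort_values(["cell_type", "sample_id"]).reset_index(drop=True)
    if exclude_low:
        out = out.loc[~out["below_min_cells"]].reset_index(drop=True)
    out.attrs["gene"] = gene
    return out


# ---------------------------------------------------------------------------
# Tukey-Kramer pairwise comparisons
# ---------------------------------------------------------------------------

def tukey_pairwise(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise group comparisons with the Tukey-Kramer adjustment.

    A one-way fit pools the within-group variance; each unordered pair (a, b)
    is tested with q = |mean_a - mean_b| / sqrt(MSE/2 * (1/n_a + 1/n_b))
    against the studentized range distribution with k groups and N - k error
    degrees of freedom (the Kramer form handles unequal group sizes).
    Groups with fewer than two observations are excluded with a warning;
    fewer than two usable groups is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [g for g in pd.unique(groups)]
    usable, dropped = [], []
    for g in levels:
        (usable if (groups == g).sum() >= 2 else dropped).append(g)
    if dropped:
        warnings.warn(f"excluding group(s) with <2 samples: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise DegenerateStatisticsError(
            f"need >=2 groups with >=2 samples (usable: {usable})"
        )
    data = {g: values[groups == g] for g in usable}
    k = len(usable)
    n_total = sum(len(v) for v in data.values())
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = sse / df_err

    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        diff = data[a].mean() - data[b].mean()
        if mse == 0:
            p = 1.0 if diff == 0 else np.nextafter(0, 1)
            q = 0.0 if diff == 0 else np.inf
        else:
            se_q = np.sqrt(mse / 2 * (1 / len(data[a]) + 1 / len(data[b])))
            q = abs(diff) / se_q
            p = float(stats.studentized_range.sf(q, k, df_err))
            p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": len(data[a]),
                "n_b": len(data[b]),
                "diff": diff,
                "q": q,
                "p_adjusted": p,
                "significant": p <= alpha,
                "stars": stars(p),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["df_error"] = df_err
    out.attrs["mse"] = mse
    out.attrs["k_groups"] = k
    return out


def _tukey_by_celltype(
    summaries: pd.DataFrame, column: str, alpha: float
) -> pd.DataFrame:
    frames = []
    for cell_type, sub in summaries.groupby("cell_type", observed=True):
        res = tukey_pairwise(sub[column].to_numpy(), sub["group"].to_numpy(), alpha=alpha)
        res.insert(0, "cell_type", cell_type)
        res.insert(1, "metric", column)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


COMPOSITION_METRICS = ("n_cells", "pct_of_sample", "n_expressing", "pct_expressing")


def composition_compare(
    summaries: pd.DataFrame, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey-Kramer four-group comparison of a per-sample composition
    metric, run within each cell type."""
    if metric not in COMPOSITION_METRICS:
        raise ConfigurationError(
            f"metric must be one of {COMPOSITION_METRICS} (got {metric!r})"
        )
    return _tukey_by_celltype(summaries, metric, alpha)


def expression_compare(summaries: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer four-group comparison of the per-sample median
    log2(normalized expression + 1), within each cell type — the
    sample-level differential-expression readout."""
    return _tukey_by_celltype(summaries, "median_log2", alpha)


# ---------------------------------------------------------------------------
# Cell-level (aggregated) differential expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellLevelDeResult:
    """One pooled-cell Wilcoxon comparison of a gene between two groups."""

    cell_type: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    p_raw: float
    p_bonferroni: float
    avg_log2fc: float
    pct_a: float
    pct_b: float
    method: str


def _rank_sum_p(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both groups are small and tie-free; otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and max(len(a), len(b)) <= exact_max_n:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(min(res.pvalue, 1.0)), "exact"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(min(res.pvalue, 1.0)), "asymptotic"


def average_log2_fold_change(a: np.ndarray, b: np.ndarray) -> float:
    """log2 ratio of group mean de-logged expression, with +1 pseudocounts:
    log2(mean(expm1(a)) + 1) - log2(mean(expm1(b)) + 1).

    Antisymmetric under swapping the groups.
    """
    return float(
        np.log2(np.expm1(a).mean() + 1.0) - np.log2(np.expm1(b).mean() + 1.0)
    )


def cell_level_de(
    ds: SingleCellDataset,
    gene: str,
    cell_type: str,
    group_a: str,
    group_b: str,
    n_comparisons: int = 1,
) -> CellLevelDeResult:
    """Wilcoxon rank-sum comparison of one gene between two groups, pooling
    every cell of ``cell_type`` per group."""
    obs = ds.adata.obs
    mask_type = (obs["cell_type"] == cell_type).to_numpy()
    out = {}
    for label, grp in (("a", group_a), ("b", group_b)):
        mask = mask_type & (obs["group"] == grp).to_numpy()
        if not mask.any():
            raise DegenerateStatisticsError(
                f"no {cell_type!r} cells in group {grp!r}"
            )
        out[label] = ds.gene_values(gene, mask=mask)
    a, b = out["a"], out["b"]
    p_raw, method = _rank_sum_p(a, b)
    return CellLevelDeResult(
        cell_type=cell_type,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_comparisons),
        avg_log2fc=average_log2_fold_change(a, b),
        pct_a=float((a > 0).mean()),
        pct_b=float((b > 0).mean()),
        method=method,
    )


def expressed_cell_types(ds: SingleCellDataset, gene: str) -> list[str]:
    """Cell types with at least one cell expressing the gene."""
    vec = ds.gene_values(gene)
    obs = ds.adata.obs
    types = []
    for ct, idx in obs.groupby("cell_type", observed=True).indices.items():
        if (vec[idx] > 0).any():
            types.append(ct)
    return sorted(types)


def cell_level_de_all(
    ds: SingleCellDataset, gene: str, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise group comparisons of the gene within every cell type
    that expresses it.

    The Bonferroni family is (number of expressing cell types) x (number of
    group pairs), e.g. 2 x 6 = 12 for two expressing types and four groups;
    comparisons lacking cells on either side are skipped (still counted in
    the family).  ``significant`` flags p_raw < alpha / n_comparisons.
    """
    types = expressed_cell_types(ds, gene)
    if not types:
        raise DegenerateStatisticsError(f"no cell type expresses {gene!r}")
    pairs = list(itertools.combinations(GROUPS, 2))
    n_comparisons = len(types) * len(pairs)
    threshold = alpha / n_comparisons
    rows = []
    for ct in types:
        for ga, gb in pairs:
            try:
                res = cell_level_de(ds, gene, ct, ga, gb, n_comparisons=n_comparisons)
            except DegenerateStatisticsError:
                continue
            rows.append(
                {
                    "cell_type": ct,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni,
                    "avg_log2fc": res.avg_log2fc,
                    "pct_a": res.pct_a,
                    "pct_b": res.pct_b,
                    "method": res.method,
                    "significant": res.p_raw < threshold,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_comparisons"] = n_comparisons
    out.attrs["threshold"] = threshold
    out.attrs["expressed_cell_types"] = types
    return out


# ---------------------------------------------------------------------------
# Bulk infected-vs-mock t-tests
# ---------------------------------------------------------------------------

def bulk_ttest(
    data: pd.DataFrame, alpha: float = 0.05, n_tests: int | None = None
) -> pd.DataFrame:
    """Per-contrast two-sided pooled t-tests on bulk normalized expression.

    ``data`` is tidy with columns ``contrast`` (e.g. cell line x MOI),
    ``condition`` in {infected, mock} and ``value``; each arm needs at least
    two replicates.  Significance applies alpha / n_tests, n_tests
    defaulting to the number of contrasts.
    """
    required = {"contrast", "condition", "value"}
    if not required <= set(data.columns):
        raise DataError(f"bulk table needs columns {sorted(required)}")
    contrasts = list(pd.unique(data["contrast"]))
    m = n_tests if n_tests is not None else len(contrasts)
    threshold = alpha / m
    rows = []
    for contrast in contrasts:
        sub = data.loc[data["contrast"] == contrast]
        inf = sub.loc[sub["condition"] == "infected", "value"].to_numpy(dtype=float)
        mock = sub.loc[sub["condition"] == "mock", "value"].to_numpy(dtype=float)
        if len(inf) < 2 or len(mock) < 2:
            raise DegenerateStatisticsError(
                f"contrast {contrast!r}: need >=2 replicates per condition "
                f"(got {len(inf)} infected, {len(mock)} mock)"
            )
        if np.ptp(np.concatenate([inf, mock])) == 0:
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(inf, mock, equal_var=True)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "contrast": contrast,
                "n_infected": len(inf),
                "n_mock": len(mock),
                "mean_infected": float(inf.mean()),
                "mean_mock": float(mock.mean()),
                "t": t_stat,
                "p": p,
                "significant": p <= threshold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_tests"] = m
    return out
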