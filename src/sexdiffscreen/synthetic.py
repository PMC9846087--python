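"""Synthetic-data generators for every pipeline input, with ground truth.

Each generator is a pure function of (config, seed): rerunning with the
same arguments reproduces its output exactly.  Defaults mirror the shape of
the motivating study design — a 172-SNP candidate panel screened in paired
sex-stratified GWAS summary statistics, a 49-tissue eQTL table and TPM
matrix, and a four-group (sex x disease) heart single-cell dataset with
6/13/12/16 samples per group and nine cell types — so that default fixtures
exercise the pipeline at realistic scale.

Counts are negative-binomial (overdispersed, the realistic stress case for
the rank test) with variance mu + alpha * mu**2; GWAS effect estimates are
normal around the true per-sex effects with their stated standard errors;
TPM is log-normal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import SnpPanel, frame_from_records, write_gwas_summary, write_snp_panel
from .singlecell import GROUPS, SingleCellDataset, save_dataset
from .tissue import TissueExpressionMatrix, write_tpm_matrix

import anndata as ad
from scipy import sparse

# Non-strand-ambiguous allele pairs used for synthesized variants.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T"))

#: GTEx-flavoured tissue labels (49) reused by the TPM and eQTL generators.
TISSUES_49 = tuple(
    [
        "muscle_skeletal",
        "heart_left_ventricle",
        "heart_atrial_appendage",
        "breast_mammary",
        "brain_cerebellum",
        "brain_cerebellar_hemisphere",
        "adipose_subcutaneous",
        "artery_tibial",
        "artery_aorta",
        "nerve_tibial",
    ]
    + [f"tissue_{i:02d}" for i in range(11, 50)]
)

CELL_TYPES_9 = (
    "cardiomyocyte",
    "vsmc",
    "fibroblast",
    "vascular_endothelial",
    "lymphatic_endothelial",
    "pericyte",
    "macrophage",
    "adipocyte",
    "neuronal",
)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Paired sex-stratified GWAS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GwasSimConfig:
    """Design of the simulated candidate-panel GWAS pair.

    One panel SNP (by default the first) carries a planted sex-differential
    effect with its standard errors pinned at ``planted_se``; all other SNPs
    are null with per-sex standard errors drawn uniformly from the stated
    ranges (female errors larger, reflecting the smaller female stratum).
    """

    n_snps: int = 172
    chrom: str = "2"
    pos_start: int = 150_000_000
    pos_step: int = 50_000
    se_range_f: tuple[float, float] = (0.08, 0.14)
    se_range_m: tuple[float, float] = (0.06, 0.10)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    #: SNP index -> (theta_f, theta_m) true per-sex effects.
    planted_effects: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (0.8, 0.0)}
    )
    planted_se: tuple[float, float] = (0.10, 0.07)
    #: Fraction of male records emitted with swapped alleles (and negated
    #: beta), to exercise harmonization.  The two representations are
    #: statistically identical.
    flip_fraction: float = 0.0
    n_cases_f: int = 283
    n_controls_f: int = 7113
    n_cases_m: int = 565
    n_controls_m: int = 6093

    def __post_init__(self) -> None:
        for lo, hi in (self.se_range_f, self.se_range_m):
            if not 0 < lo <= hi:
                raise ConfigurationError(f"invalid se range ({lo}, {hi})")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if any(i >= self.n_snps for i in self.planted_effects):
            raise ConfigurationError("planted SNP index beyond n_snps")


@dataclass
class SimulatedGwas:
    female: pd.DataFrame
    male: pd.DataFrame
    panel: SnpPanel
    truth: pd.DataFrame


def simulate_paired_gwas(
    config: GwasSimConfig | None = None, seed: int = 0
) -> SimulatedGwas:
    """Draw per-sex effect estimates beta_sex ~ N(theta_sex, se_sex^2) for
    every panel SNP, with Wald p-values, synthesized alleles, shared EAF and
    evenly spaced positions.  The truth table records (theta_f, theta_m,
    delta) per SNP."""
    cfg = config or GwasSimConfig()
    rng = _rng(seed)
    n = cfg.n_snps
    snp_ids = np.array([f"rs{1_000_000 + i}" for i in range(n)])
    pos = cfg.pos_start + cfg.pos_step * np.arange(n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    eaf = rng.uniform(*cfg.eaf_range, size=n)

    theta_f = np.zeros(n)
    theta_m = np.zeros(n)
    se_f = rng.uniform(*cfg.se_range_f, size=n)
    se_m = rng.uniform(*cfg.se_range_m, size=n)
    for i, (tf, tm) in cfg.planted_effects.items():
        theta_f[i], theta_m[i] = tf, tm
        se_f[i], se_m[i] = cfg.planted_se

    beta_f = rng.normal(theta_f, se_f)
    beta_m = rng.normal(theta_m, se_m)
    p_f = 2 * stats.norm.sf(np.abs(beta_f / se_f))
    p_m = 2 * stats.norm.sf(np.abs(beta_m / se_m))

    def _frame(beta, se, p, n_cases, n_controls, flip_mask):
        df = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": cfg.chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p": np.clip(p, np.nextafter(0, 1), 1.0),
                "n_cases": n_cases,
                "n_controls": n_controls,
            }
        )
        if flip_mask is not None and flip_mask.any():
            df.loc[flip_mask, ["effect_allele", "other_allele"]] = df.loc[
                flip_mask, ["other_allele", "effect_allele"]
            ].to_numpy()
            df.loc[flip_mask, "beta"] = -df.loc[flip_mask, "beta"]
            df.loc[flip_mask, "eaf"] = 1.0 - df.loc[flip_mask, "eaf"]
        df["pos"] = df["pos"].astype("Int64")
        df["n_cases"] = df["n_cases"].astype("Int64")
        df["n_controls"] = df["n_controls"].astype("Int64")
        df["chrom"] = df["chrom"].astype("string")
        return df

    flip = rng.random(n) < cfg.flip_fraction
    female = _frame(beta_f, se_f, p_f, cfg.n_cases_f, cfg.n_controls_f, None)
    male = _frame(beta_m, se_m, p_m, cfg.n_cases_m, cfg.n_controls_m, flip)
    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "theta_f": theta_f,
            "theta_m": theta_m,
            "delta": theta_f - theta_m,
            "se_f": se_f,
            "se_m": se_m,
            "planted": theta_f != theta_m,
        }
    )
    return SimulatedGwas(
        female=female, male=male, panel=SnpPanel(snp_ids=tuple(snp_ids)), truth=truth
    )


# ---------------------------------------------------------------------------
# Single-cell four-group dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScSimConfig:
    """Design of the simulated four-group heart single-cell dataset.

    Sample counts default to the study design (6 case females, 13 case
    males, 12 control females, 16 control males).  Per-sample cell-type
    composition is Dirichlet-multinomial around ``base_composition``; counts
    are negative-binomial with variance mu + dispersion * mu**2.  The target
    gene is expressed only in ``target_cell_type`` (strongly) and
    ``secondary_cell_type`` (weakly); its mean is multiplied by
    ``interaction_factor`` in cells of ``affected_group`` x
    ``target_cell_type`` — the planted sex x disease interaction.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "case_female": 6,
            "case_male": 13,
            "control_female": 12,
            "control_male": 16,
        }
    )
    cell_types: tuple[str, ...] = CELL_TYPES_9
    base_composition: tuple[float, ...] = (
        0.30, 0.02, 0.25, 0.15, 0.04, 0.10, 0.08, 0.04, 0.02,
    )
    dirichlet_concentration: float = 150.0
    cells_per_sample: int = 500
    n_genes: int = 30
    target_gene: str = "SPEG"
    target_cell_type: str = "cardiomyocyte"
    secondary_cell_type: str = "vsmc"
    target_mean: float = 0.6
    secondary_mean: float = 0.3
    dispersion: float = 0.5
    affected_group: str = "case_female"
    interaction_factor: float = 2.0
    #: Optional planted composition shift: (group, cell_type, factor).
    composition_shift: tuple[str, str, float] | None = None

    def __post_init__(self) -> None:
        if self.interaction_factor <= 0 or self.dispersion <= 0:
            raise ConfigurationError("multipliers and dispersions must be > 0")
        if len(self.base_composition) != len(self.cell_types):
            raise ConfigurationError("base_composition must match cell_types")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ConfigurationError("base_composition must sum to 1")
        if self.affected_group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.affected_group!r}")


@dataclass
class SimulatedSc:
    dataset: SingleCellDataset
    truth: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion*mu^2."""
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_sc_dataset(config: ScSimConfig | None = None, seed: int = 0) -> SimulatedSc:
    cfg = config or ScSimConfig()
    rng = _rng(seed)
    genes = [cfg.target_gene] + [f"gene_{i:03d}" for i in range(1, cfg.n_genes)]
    # Background gene means, shared across cell types and groups (null genes);
    # the first background gene is a highly expressed housekeeping anchor so
    # cells essentially never have zero totals.
    bg_means = np.exp(rng.normal(np.log(0.3), 0.8, size=cfg.n_genes - 1))
    bg_means[0] = 5.0

    obs_rows = []
    for group in GROUPS:
        comp = np.asarray(cfg.base_composition, dtype=float)
        if cfg.composition_shift is not None:
            g, ct, factor = cfg.composition_shift
            if group == g:
                comp = comp.copy()
                comp[cfg.cell_types.index(ct)] *= factor
                comp = comp / comp.sum()
        for s in range(cfg.n_per_group[group]):
            sample_id = f"{group}_s{s:02d}"
            disease, sex = group.rsplit("_", 1)
            props = rng.dirichlet(comp * cfg.dirichlet_concentration)
            total = rng.poisson(cfg.cells_per_sample)
            counts = rng.multinomial(total, props)
            for ct, k in zip(cfg.cell_types, counts):
                for c in range(k):
                    obs_rows.append((f"{sample_id}_{ct}_{c}", ct, sample_id, sex, disease))
    obs = pd.DataFrame(
        obs_rows, columns=["cell_id", "cell_type", "sample_id", "sex", "disease"]
    ).set_index("cell_id")
    n_cells = len(obs)

    X = np.empty((n_cells, cfg.n_genes), dtype=np.int64)
    for j, mu in enumerate(bg_means, start=1):
        X[:, j] = _nb_draw(rng, np.full(n_cells, mu), cfg.dispersion)
    target_mu = np.zeros(n_cells)
    ct_arr = obs["cell_type"].to_numpy()
    group_arr = (obs["disease"] + "_" + obs["sex"]).to_numpy()
    target_mu[ct_arr == cfg.target_cell_type] = cfg.target_mean
    target_mu[ct_arr == cfg.secondary_cell_type] = cfg.secondary_mean
    affected = (ct_arr == cfg.target_cell_type) & (group_arr == cfg.affected_group)
    target_mu[affected] *= cfg.interaction_factor
    X[:, 0] = np.where(target_mu > 0, _nb_draw(rng, target_mu, cfg.dispersion), 0)

    adata = ad.AnnData(
        X=sparse.csr_matrix(X),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth_rows = [
        {
            "kind": "expression",
            "gene": cfg.target_gene,
            "cell_type": cfg.target_cell_type,
            "group": cfg.affected_group,
            "factor": cfg.interaction_factor,
        }
    ]
    if cfg.composition_shift is not None:
        g, ct, factor = cfg.composition_shift
        truth_rows.append(
            {"kind": "composition", "gene": "", "cell_type": ct, "group": g, "factor": factor}
        )
    return SimulatedSc(
        dataset=SingleCellDataset(adata=adata), truth=pd.DataFrame(truth_rows)
    )


# ---------------------------------------------------------------------------
# Bulk TPM matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TpmSimConfig:
    """Log-normal TPM for one gene across many tissues, by sex.

    TPM = exp(N(mu_tissue + sex_effect * [female], sigma^2)); planted sex
    effects are additive on the natural-log scale for females.
    """

    tissues: tuple[str, ...] = TISSUES_49
    samples_per_sex: int = 30
    gene: str = "SPEG"
    mu_range: tuple[float, float] = (0.5, 3.5)
    sigma: float = 1.0
    planted_sex_effects: dict[str, float] = field(
        default_factory=lambda: {"breast_mammary": 1.5}
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        unknown = set(self.planted_sex_effects) - set(self.tissues)
        if unknown:
            raise ConfigurationError(f"planted effects for unknown tissues: {unknown}")


@dataclass
class SimulatedTpm:
    matrix: TissueExpressionMatrix
    truth: pd.DataFrame


def simulate_tpm(config: TpmSimConfig | None = None, seed: int = 0) -> SimulatedTpm:
    cfg = config or TpmSimConfig()
    rng = _rng(seed)
    cols, tissues, sexes, values = [], [], [], []
    truth_rows = []
    for tissue in cfg.tissues:
        mu = rng.uniform(*cfg.mu_range)
        effect = cfg.planted_sex_effects.get(tissue, 0.0)
        truth_rows.append({"tissue": tissue, "mu": mu, "sex_effect": effect})
        for sex in ("female", "male"):
            shift = effect if sex == "female" else 0.0
            draws = np.exp(rng.normal(mu + shift, cfg.sigma, size=cfg.samples_per_sex))
            for i, v in enumerate(draws):
                cols.append(f"{tissue}_{sex}_{i:03d}")
                tissues.append(tissue)
                sexes.append(sex)
                values.append(v)
    tpm = pd.DataFrame([values], index=pd.Index([cfg.gene], name="gene"), columns=cols)
    samples = pd.DataFrame(
        {"tissue": tissues, "sex": sexes}, index=pd.Index(cols, name="sample_id")
    )
    return SimulatedTpm(
        matrix=TissueExpressionMatrix(tpm=tpm, samples=samples),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Multi-tissue eQTL table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EqtlSimConfig:
    """Per-tissue eQTL records for one SNP x gene with a chosen true-NES
    vector; observed NES is the true value plus N(0, 1/n) sampling noise,
    p is the Wald test of the observed NES, and the m-value is a monotone
    map of the evidence (high where a true effect exists)."""

    tissues: tuple[str, ...] = TISSUES_49
    gene: str = "SPEG"
    snp_id: str = "rs1000000"
    n_range: tuple[int, int] = (70, 700)
    true_nes: dict[str, float] = field(
        default_factory=lambda: {
            "muscle_skeletal": -0.35,
            "brain_cerebellum": 0.25,
            "brain_cerebellar_hemisphere": 0.28,
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.true_nes) - set(self.tissues)
        if unknown:
            raise ConfigurationError(f"true NES for unknown tissues: {unknown}")


@dataclass
class SimulatedEqtl:
    records: pd.DataFrame
    truth: pd.DataFrame


def simulate_eqtl_table(config: EqtlSimConfig | None = None, seed: int = 0) -> SimulatedEqtl:
    cfg = config or EqtlSimConfig()
    rng = _rng(seed)
    rows, truth_rows = [], []
    for tissue in cfg.tissues:
        n = int(rng.integers(*cfg.n_range))
        true = cfg.true_nes.get(tissue, 0.0)
        se = 1.0 / np.sqrt(n)
        nes = rng.normal(true, se)
        z = nes / se
        p = float(np.clip(2 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
        # heuristic posterior: strong |z| -> m near 1, weak -> near 0
        m_value = float(1.0 / (1.0 + np.exp(-(abs(z) - 1.5))))
        rows.append(
            {
                "gene": cfg.gene,
                "snp_id": cfg.snp_id,
                "tissue": tissue,
                "sample_size": n,
                "nes": nes,
                "p_nominal": p,
                "m_value": m_value,
            }
        )
        truth_rows.append({"tissue": tissue, "true_nes": true, "n": n})
    return SimulatedEqtl(records=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Planted-truth recovery benchmark
# ---------------------------------------------------------------------------

def planted_recovery_rate(
    n_seeds: int = 100,
    seed0: int = 0,
    gwas_config: GwasSimConfig | None = None,
    sc_config: ScSimConfig | None = None,
    alpha: float = 0.05,
) -> dict:
    """Run the screen and the cell-level DE end to end on freshly simulated
    bundles over ``n_seeds`` consecutive seeds, scoring each replicate
    against its truth table.

    A GWAS replicate succeeds when the Bonferroni-significant set equals the
    planted set exactly; a single-cell replicate succeeds when the planted
    contrast (affected group vs the same-sex control group in the target
    cell type) passes the cell-level bound.  Returns per-stage and joint
    success fractions.
    """
    import warnings

    from .gwas_io import harmonize_pair
    from .screen import screen_panel
    from .singlecell import cell_level_de_all, normalize_counts

    sc_cfg = sc_config or ScSimConfig()
    disease, sex = sc_cfg.affected_group.rsplit("_", 1)
    other_disease = "control" if disease == "case" else "case"
    contrast = frozenset((sc_cfg.affected_group, f"{other_disease}_{sex}"))

    gwas_ok = sc_ok = joint_ok = 0
    for seed in range(seed0, seed0 + n_seeds):
        sim = simulate_paired_gwas(gwas_config, seed=seed)
        paired = harmonize_pair(sim.female, sim.male)
        report = screen_panel(paired, sim.panel, alpha=alpha)
        truth_set = set(sim.truth.loc[sim.truth["planted"], "snp_id"])
        g_hit = set(report.significant["snp_id"]) == truth_set
        gwas_ok += g_hit

        scsim = simulate_sc_dataset(sc_cfg, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = normalize_counts(scsim.dataset)
        de = cell_level_de_all(ds, sc_cfg.target_gene, alpha=alpha)
        hit = de.loc[
            (de["cell_type"] == sc_cfg.target_cell_type)
            & (de.apply(lambda r: frozenset((r.group_a, r.group_b)) == contrast, axis=1))
        ]
        s_hit = bool(len(hit)) and bool(hit["significant"].all())
        sc_ok += s_hit
        joint_ok += g_hit and s_hit
    return {
        "n_seeds": n_seeds,
        "gwas_recovery": gwas_ok / n_seeds,
        "sc_recovery": sc_ok / n_seeds,
        "joint_recovery": joint_ok / n_seeds,
    }


# ---------------------------------------------------------------------------
# File bundles
# ---------------------------------------------------------------------------

def write_bundle(kind: str, out_dir: str | Path, seed: int = 0, config=None) -> dict[str, Path]:
    """Simulate one input kind and write it in the formats the readers
    consume, plus its truth table.  Returns the emitted paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if kind == "gwas":
        sim = simulate_paired_gwas(config, seed=seed)
        paths["female"] = out / "gwas_female.tsv"
        paths["male"] = out / "gwas_male.tsv"
        paths["panel"] = out / "panel.tsv"
        paths["truth"] = out / "gwas_truth.tsv"
        write_gwas_summary(sim.female, paths["female"])
        write_gwas_summary(sim.male, paths["male"])
        write_snp_panel(sim.panel, paths["panel"])
        sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    elif kind == "sc":
        sim = simulate_sc_dataset(config, seed=seed)
        paths["counts"] = out / "sc_counts.mtx"
        paths["cells"] = out / "sc_cells.tsv"
        paths["genes"] = out / "sc_genes.tsv"
        paths["truth"] = out / "sc_truth.tsv"
        save_dataset(sim.dataset, paths["counts"], paths["cells"], paths["genes"])
        sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    elif kind == "tpm":
        sim = simulate_tpm(config, seed=seed)
        paths["matrix"] = out / "tpm_matrix.tsv"
        paths["attributes"] = out / "tpm_samples.tsv"
        paths["truth"] = out / "tpm_truth.tsv"
        write_tpm_matrix(sim.matrix, paths["matrix"], paths["attributes"])
        sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    elif kind == "eqtl":
        sim = simulate_eqtl_table(config, seed=seed)
        paths["records"] = out / "eqtl_records.tsv"
        paths["truth"] = out / "eqtl_truth.tsv"
        sim.records.to_csv(paths["records"], sep="\t", index=False)
        sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    else:
        raise ConfigurationError(f"unknown simulation kind {kind!r}")
    return paths
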