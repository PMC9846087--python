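# sexdiffscreen

Sex-biased differential-association screening of GWAS summary statistics,
with cis-eQTL, tissue-expression and single-cell differential-expression
follow-up.

## The problem

Several diseases — hypertension and severe COVID-19 among them — show
sex-biased prevalence and severity, suggesting that some shared genetic risk
factors act differently in women and men. When a GWAS has been run
separately by sex, a candidate variant's per-stratum effect estimates
(β_f, se_f) and (β_m, se_m) can be compared directly: under the null of one
shared effect, with independent strata,

    ΔZ = (β_f − β_m) / √(se_f² + se_m²)

is standard normal, with a two-sided p-value 2·Φ(−|ΔZ|). Screening a panel
of *m* candidate SNPs (for example, hypertension-associated cis-eQTLs
evaluated in sex-stratified severe-COVID GWASs) at the Bonferroni bound
α/m yields sex-biased candidates; a hit is then followed up by

1. a local 1-Mbp window scan for suggestive (p < 10⁻³) signals per sex,
2. multi-tissue cis-eQTL annotation (signed NES oriented on the risk
   allele, per-tissue bound α/n_tissues, cross-tissue consistency via the
   m-value > 0.5 rule),
3. per-tissue sex differential expression of the mapped gene on bulk TPM
   (two-group ANOVA, F = t²), and
4. a dual-level single-cell analysis in a sex × disease four-group design:
   sample-level pseudobulk summaries (median log2(normalized + 1), cell
   counts/shares, percent expressing) compared with Tukey-Kramer pairwise
   contrasts, and cell-level pooled Wilcoxon rank-sum DE with average log2
   fold change, plus bulk infected-vs-mock t-tests.

The package implements every stage as a library with a thin
`sexdiff-screen` CLI, and ships generators that synthesize all five input
kinds with known ground truth, so the full pipeline is testable without
access to restricted cohort data.

## Worked example

```python
>>> import sexdiffscreen as sds
>>> res = sds.delta_z(0.36, 0.10, -0.08, 0.07)   # female vs male estimates
>>> round(res.delta_z, 3), float(f"{res.p_diff:.1e}")
(3.605, 0.00031)
>>> sds.bonferroni_threshold(0.05, 172)
0.00029069767441860465
```

A female log-odds estimate of 0.36 (se 0.10) against a male estimate of
−0.08 (se 0.07) gives ΔZ = 3.605, p ≈ 3.1×10⁻⁴ — just above the 172-SNP
panel bound 0.05/172 ≈ 2.9×10⁻⁴ when computed from these rounded inputs
(unrounded summary statistics push it past the bound; see
`docs/methods.md`).

End to end on synthetic data:

```bash
sexdiff-screen simulate --kind gwas --seed 1 --out-dir sim
sexdiff-screen screen --female sim/gwas_female.tsv --male sim/gwas_male.tsv \
    --panel sim/panel.tsv --out screen
```

prints

```json
{"alpha": 0.05, "m_tests": 172, "threshold": 0.00029069767441860465,
 "n_significant": 1, "significant_snps": ["rs1000000"], "dropped": []}
```

recovering exactly the one SNP the generator planted with a sex-differential
effect (`sim/gwas_truth.tsv`). `sexdiff-screen run --config run.yaml` chains
all stages (screen → window → eQTL → tissue → single-cell → bulk) and
writes per-stage TSVs plus a JSON run report with input digests and top
hits.

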