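# Methods

## The differential-association model

The screen assumes each sex stratum yields an asymptotically normal effect
estimate for every SNP: β̂_s ~ N(β_s, se_s²), s ∈ {f, m}, with the two
strata independent (they contain disjoint individuals from one cohort).
Under H₀: β_f = β_m,

ΔZ = (β̂_f − β̂_m) / √(se_f² + se_m²) ~ N(0, 1),

tested two-sided with p = 2·Φ(−|ΔZ|). The implementation deliberately uses
the absolute value: the naive "2·pnorm(−ΔZ)" form exceeds 1 for negative
statistics and is not a probability. No heterogeneity statistic (Cochran's
Q) or shrinkage is applied — the screen is the plain Wald contrast, which
is also what makes its calibration exactly checkable against the normal
closed forms (type-I rate α; power 1 − Φ(z_{α/2} − λ) + Φ(−z_{α/2} − λ)
with λ = δ/√(se_f² + se_m²)).

A note on rounding: with per-stratum estimates quoted to two decimals —
(0.36, 0.10) female, (−0.08, 0.07) male — the statistic is 3.605
(p ≈ 3.1×10⁻⁴). Published analyses working from unrounded summary
statistics can report a larger value (3.75, p ≈ 1.8×10⁻⁴) for the same
variant; both round-trips are covered in the tests and the package never
forces agreement between the two.

## Multiplicity conventions

Every stage uses a plain Bonferroni bound α/m with α = 0.05 by default:

* panel screen — m = number of panel SNPs actually tested (a flag forces
  the nominal panel size, e.g. 172, when SNPs are missing); the comparison
  is strict (p < α/m);
* eQTL tissues and tissue-expression ANOVA — m = number of tissues in the
  supplied table (never hard-coded to 49); the comparison is inclusive
  (p ≤ α/m), matching the "p ≤ 0.05/k" reporting convention, and both
  nominal and adjusted flags are emitted because practice mixes the two;
* cell-level single-cell DE — m = (cell types with any expression) ×
  (group pairs), e.g. 2 × 6 = 12;
* bulk contrasts — m = number of infected-vs-mock contrasts (6 by
  default).

## Harmonization

Strata are paired on SNP id; a male record whose alleles are swapped
relative to the female record has its β negated, EAF complemented and
alleles swapped (an involution). Allele sets matching neither directly nor
after a swap abort with the offending SNPs listed. Strand-ambiguous A/T and
C/G variants cannot be distinguished from opposite-strand reports from
frequency alone; since paired sex strata normally derive from a single
cohort on one array, the default policy keeps them under a same-strand
assumption, with a drop policy available. Windows are 1-based closed
intervals of total width *w* centred on a SNP; the MAF filter
min(EAF, 1−EAF) > 0.05 is strict.

## Tissue expression

Per tissue, expression of one gene is compared between the sexes with the
classical pooled one-way ANOVA, equivalent to the pooled t-test (F = t²)
for two groups; a Welch flag relaxes the equal-variance assumption. The
default scale is log2(TPM+1) — TPM is heavily right-skewed and the log
stabilizes variance — with `transform="none"` available since the source
procedure's scale is a modelling choice, not a mathematical necessity.
Tissues with fewer than two samples of either sex are reported untested
rather than dropped. Degenerate all-equal inputs are reported as F = 0,
p = 1 (no evidence of a difference) rather than NaN.

## Single-cell procedure

Counts are log-normalized per cell: x = ln(1 + c/total × 10⁴). A cell
expresses the gene iff x > 0, equivalently iff its raw count is nonzero.
Sample-level summaries report the median of log2(normalized + 1); because
log2(c/total×10⁴ + 1) = x/ln 2 and medians commute with monotone maps, the
median is computed on the natural-log layer and rescaled, not recomputed.

Sample-level inference treats the sample as the unit of replication: for
each cell type, a metric (median expression, cell count, composition share,
expressing count/share) is compared across the four sex × disease groups
with all pairwise Tukey-Kramer contrasts — q = |x̄_a − x̄_b| /
√(MSE/2·(1/n_a + 1/n_b)) against the studentized-range distribution with
k groups and N − k error df, MSE pooled from the one-way fit. Groups with
fewer than two samples are excluded with a warning. Sample × cell-type
strata with fewer than 100 cells are flagged, not excluded (an exclusion
switch exists): small strata make the per-sample median unstable, but
dropping them silently would bias group comparisons.

Cell-level inference pools all cells of a type per group and applies the
two-sided Wilcoxon rank-sum test on the normalized values: exact
enumeration when both groups have ≤ 25 cells and the pooled values are
tie-free, otherwise the normal approximation with midrank tie correction
and continuity correction (the exact path refuses ties). The average log2
fold change follows the de-log/pseudocount convention
log2(mean(eˣ−1)+1) − log2(mean(eˣ−1)+1), antisymmetric under swapping the
groups. Pooling cells treats cells as exchangeable within a group and
ignores within-sample correlation — it is powerful but anticonservative
relative to the sample-level analysis, which is exactly why both levels are
reported.

## Synthetic data

The generators emulate the statistical structure each stage consumes, at
the study's shape: a 172-SNP panel with sex-stratified normal effect
estimates (female standard errors drawn from (0.08, 0.14), male from
(0.06, 0.10), reflecting the smaller female stratum of 283 cases/7,113
controls vs 565/6,093); a 49-tissue eQTL table and log-normal TPM matrix
(30 samples per sex per tissue); and a four-group heart single-cell dataset
with 6/13/12/16 samples per group (the methods-section sizes; the source
figure legend gives slightly different counts — 13/16 healthy, 6/12
COVID-19 — and the generator follows the methods text), nine cell types
with Dirichlet-multinomial composition (concentration 150, ~500 cells per
sample), and negative-binomial counts (variance μ + 0.5 μ²; overdispersion
is the realistic stress case for the rank test). The target gene is
expressed only in cardiomyocytes (mean 0.6/cell) and weakly in VSMC
(0.3/cell), mirroring a myocyte-restricted gene with a minority of
expressing cells; the planted sex × disease interaction multiplies its
cardiomyocyte mean in case females (default ×2).

The default planted GWAS effect is (θ_f, θ_m) = (0.8, 0) with the hit
SNP's standard errors pinned at (0.10, 0.07), i.e. λ ≈ 6.5 and closed-form
power ≈ 0.998 at the 0.05/172 bound. This is a deliberate
recovery-benchmark choice: at an effect of the size actually observable in
a cohort this small (δ ≈ 0.44, λ ≈ 3.6) the closed form gives only ≈ 0.49
power at the panel bound, so exact recovery of the planted set cannot be a
high-probability event; the power claims at δ = 0.44 are checked
separately against the closed form. Even with near-unit power, exact
set-equality over 171 null SNPs carries an irreducible family-wise
false-positive rate of 1 − (1 − α/172)^171 ≈ 4.9%, so the expected
exact-recovery fraction is ≈ 0.95 by construction.

What the generators do *not* emulate: LD between SNPs (effect estimates are
independent), genotype data, sequencing noise, doublets, batch effects, or
within-sample cell-cell correlation beyond the shared library-size scaling.
Passing tests therefore validate the statistical machinery and its
calibration under the assumed sampling models, not robustness to those
real-data violations.

## Numerical and design choices

* Ties in sorted reports are broken by SNP id / tissue name for
  deterministic output; stable sorts throughout.
* p-values are clipped into (0, 1]; degenerate zero-variance Tukey inputs
  give p = 1 when the difference is 0 and the smallest positive float
  otherwise.
* The m-value (cross-tissue posterior) is consumed as published and never
  recomputed; consistency is the strict m > 0.5 rule.
* Bonferroni quotients are returned exactly; rounding (3e-4, 0.001, 4e-3,
  0.008) is presentation only.
* eQTL release versions (e.g. GTEx V7 vs V8) are treated as a property of
  the supplied table; the package does not arbitrate between releases.
* Problem sizes in the acceptance script (50,000 null SNPs; 8,000 power
  replicates; 100 end-to-end bundles of 172 SNPs and ~23,000 cells) were
  chosen so each closed-form comparison has Monte-Carlo error well inside
  its tolerance while the whole script completes in well under a minute of
  simulation time per block.

## Known limitations

* The sample-level model is a one-way fit on the four groups only — no
  covariates (age, batch, sequencing depth), matching the minimal design it
  reproduces.
* The cell-level Wilcoxon treats cells as independent; p-values there are
  optimistic in the presence of sample effects.
* Colocalization, eQTL mapping, LD-aware windowing and trajectory analyses
  are out of scope; cell-type labels and embeddings are inputs, never
  computed.
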