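"""Normalization, sample-level roll-ups, Tukey-Kramer comparisons and
cell-level Wilcoxon DE."""

import itertools
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from sexdiffscreen import (
    DataError,
    DegenerateStatisticsError,
    SingleCellDataset,
    average_log2_fold_change,
    bulk_ttest,
    cell_level_de,
    cell_level_de_all,
    composition_compare,
    expression_compare,
    normalize_counts,
    stars,
    summarize_samples,
    tukey_pairwise,
)
from sexdiffscreen.singlecell import _rank_sum_p, load_dataset
from sexdiffscreen.synthetic import save_dataset


def build_dataset(cells, counts, genes=("SPEG", "other")):
    """cells: iterable of (cell_type, sample_id, sex, disease)."""
    obs = pd.DataFrame(
        list(cells),
        columns=["cell_type", "sample_id", "sex", "disease"],
        index=[f"c{i}" for i in range(len(cells))],
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(np.asarray(counts, dtype=float)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
    )
    return SingleCellDataset(adata=adata)


class TestNormalizeCounts:
    def test_hand_arithmetic(self):
        ds = build_dataset(
            [("cm", "s1", "female", "case")], [[1, 1, 2]], genes=("a", "b", "c")
        )
        normalize_counts(ds, scale=1e4)
        vals = np.asarray(ds.lognorm().todense()).ravel()
        assert vals[2] == pytest.approx(np.log(1 + 2 / 4 * 1e4))
        assert vals[0] == pytest.approx(np.log(1 + 1 / 4 * 1e4))

    def test_zero_count_stays_zero(self):
        ds = build_dataset([("cm", "s1", "female", "case")], [[0, 5]])
        normalize_counts(ds)
        assert ds.gene_values("SPEG")[0] == 0.0

    def test_doubling_counts_is_invariant(self):
        ds1 = build_dataset([("cm", "s1", "female", "case")], [[1, 3]])
        ds2 = build_dataset([("cm", "s1", "female", "case")], [[2, 6]])
        normalize_counts(ds1)
        normalize_counts(ds2)
        np.testing.assert_allclose(
            np.asarray(ds1.lognorm().todense()), np.asarray(ds2.lognorm().todense())
        )

    def test_zero_total_cells_dropped_with_warning(self):
        ds = build_dataset(
            [("cm", "s1", "female", "case"), ("cm", "s1", "female", "case")],
            [[0, 0], [1, 1]],
        )
        with pytest.warns(UserWarning, match="zero total"):
            normalize_counts(ds)
        assert ds.n_cells == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError, match="nonnegative"):
            build_dataset([("cm", "s1", "female", "case")], [[-1, 2]])


class TestSummarizeSamples:
    def test_toy_fractions(self):
        cells = [("A", "s1", "female", "case")] * 10
        counts = [[1, 1]] * 3 + [[0, 1]] * 7  # 3 of 10 express the gene
        ds = build_dataset(cells, counts)
        normalize_counts(ds)
        summ = summarize_samples(ds, "SPEG")
        row = summ.iloc[0]
        assert row.n_cells == 10
        assert row.pct_expressing == pytest.approx(0.30)
        assert row.pct_of_sample == 1.0

    def test_pct_of_sample_across_types(self):
        cells = [("A", "s1", "f", "case")] * 0  # placeholder
        cells = [("A", "s1", "female", "case")] * 8 + [
            ("B", "s1", "female", "case")
        ] * 2
        ds = build_dataset(cells, [[1, 1]] * 10)
        normalize_counts(ds)
        summ = summarize_samples(ds, "SPEG").set_index("cell_type")
        assert summ.loc["A", "pct_of_sample"] == pytest.approx(0.80)
        assert summ.loc["B", "pct_of_sample"] == pytest.approx(0.20)

    def test_matches_per_cell_brute_force(self, small_sc_dataset):
        """Roll-ups on a seeded dataset equal an explicit per-cell tally."""
        ds = small_sc_dataset.dataset
        summ = summarize_samples(ds, "SPEG")
        vec = ds.gene_values("SPEG")
        obs = ds.adata.obs
        for _, row in summ.sample(10, random_state=0).iterrows():
            mask = (
                (obs["sample_id"] == row.sample_id)
                & (obs["cell_type"] == row.cell_type)
            ).to_numpy()
            assert row.n_cells == mask.sum()
            assert row.n_expressing == (vec[mask] > 0).sum()
            assert row.median_log2 == pytest.approx(
                np.median(vec[mask]) / np.log(2)
            )
            assert row.pct_of_sample == pytest.approx(
                mask.sum() / (obs["sample_id"] == row.sample_id).sum()
            )

    def test_cell_conservation(self, small_sc_dataset):
        """Per sample, cell counts over cell types sum to the sample total
        and the composition shares sum to one."""
        ds = small_sc_dataset.dataset
        summ = summarize_samples(ds, "SPEG")
        totals = ds.adata.obs.groupby("sample_id", observed=True).size()
        by_sample = summ.groupby("sample_id")
        for sample_id, sub in by_sample:
            assert sub["n_cells"].sum() == totals[sample_id]
            assert sub["pct_of_sample"].sum() == pytest.approx(1.0)

    def test_median_is_on_log2_scale(self):
        # one expressing cell: median over a single cell equals its value
        ds = build_dataset([("A", "s1", "female", "case")], [[3, 1]])
        normalize_counts(ds, scale=100)
        summ = summarize_samples(ds, "SPEG")
        expected = np.log(1 + 3 / 4 * 100) / np.log(2)
        assert summ.iloc[0].median_log2 == pytest.approx(expected)

    def test_min_cells_flag_and_exclusion(self, small_sc_dataset):
        summ = summarize_samples(small_sc_dataset.dataset, "SPEG", min_cells=60)
        assert summ["below_min_cells"].any()
        kept = summarize_samples(
            small_sc_dataset.dataset, "SPEG", min_cells=60, exclude_low=True
        )
        assert not kept["below_min_cells"].any()


class TestTukeyPairwise:
    def test_identical_groups_all_p_one(self):
        values = [5.0] * 9
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = tukey_pairwise(values, groups)
        assert (out["p_adjusted"] == 1.0).all()

    def test_three_group_toy_flags_only_far_group(self):
        values = [1, 2, 3, 2, 3, 4, 10, 11, 12]
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = tukey_pairwise(values, groups, alpha=0.05).set_index(
            ["group_a", "group_b"]
        )
        assert out.loc[("A", "C"), "significant"]
        assert out.loc[("B", "C"), "significant"]
        assert not out.loc[("A", "B"), "significant"]
        # studentized-range oracle for the A-B pair: q = |1|/sqrt(MSE/3)
        q_ab = 1.0 / np.sqrt(1.0 / 3)
        assert out.loc[("A", "B"), "p_adjusted"] == pytest.approx(
            stats.studentized_range.sf(q_ab, 3, 6)
        )

    def test_balanced_two_groups_equal_unadjusted_t(self):
        """With two groups the Tukey p collapses to the plain t-test p
        (q = sqrt(2)*|t| identity)."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        out = tukey_pairwise(np.r_[a, b], ["a"] * 6 + ["b"] * 6)
        t = stats.ttest_ind(a, b, equal_var=True)
        assert out.loc[0, "p_adjusted"] == pytest.approx(t.pvalue, rel=1e-6)

    def test_matches_statsmodels_reference(self):
        """Unequal-n three-group case agrees with the statsmodels
        Tukey-Kramer implementation."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(5)
        values = np.r_[
            rng.normal(0, 1, 4), rng.normal(1, 1, 7), rng.normal(0.5, 1, 5)
        ]
        groups = ["a"] * 4 + ["b"] * 7 + ["c"] * 5
        ours = tukey_pairwise(values, groups)
        ref = sm.pairwise_tukeyhsd(values, groups)
        np.testing.assert_allclose(
            ours["p_adjusted"].to_numpy(), ref.pvalues, rtol=1e-6, atol=1e-9
        )

    def test_small_group_excluded_with_warning(self):
        values = [1, 2, 3, 2, 3, 4, 99]
        groups = ["a"] * 3 + ["b"] * 3 + ["tiny"]
        with pytest.warns(UserWarning, match="tiny"):
            out = tukey_pairwise(values, groups)
        assert set(out["group_a"]) | set(out["group_b"]) == {"a", "b"}

    def test_fewer_than_two_usable_groups_is_error(self):
        with pytest.raises(DegenerateStatisticsError):
            tukey_pairwise([1, 2, 3, 9], ["a", "a", "a", "b"])

    def test_stars_convention(self):
        assert stars(0.04) == "*"
        assert stars(0.009) == "**"
        assert stars(0.0009) == "***"
        assert stars(0.00009) == "****"
        assert stars(0.2) == "ns"


def enumeration_rank_sum_p(a, b):
    """Independent oracle: exact two-sided rank-sum p by enumerating every
    assignment of the pooled ranks to group a."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(a)
    obs = ranks[:n].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n)]
    )
    lo = (sums <= obs).mean()
    hi = (sums >= obs).mean()
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_textbook_example(self):
        p, method = _rank_sum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert method == "exact"
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_enumeration(self, seed):
        """The exact p equals brute force over all rank splits for random
        tie-free samples with up to 8 per group."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 9, size=2)
        pooled = rng.permutation(np.arange(n + m, dtype=float) + rng.normal(0, 0.01, n + m))
        a, b = pooled[:n], pooled[n:]
        p, method = _rank_sum_p(a, b)
        assert method == "exact"
        assert p == pytest.approx(enumeration_rank_sum_p(a, b))

    def test_ties_fall_back_to_asymptotic(self):
        p, method = _rank_sum_p(np.array([1.0, 1, 2]), np.array([2.0, 3, 4]))
        assert method == "asymptotic"
        assert 0 < p <= 1

    def test_exact_close_to_asymptotic_at_n20(self):
        """Exact and normal-approximation p agree within 10% relative for
        samples of 20 per group."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.6, 1, 20)
        p_exact, m1 = _rank_sum_p(a, b, exact_max_n=25)
        p_asym, m2 = _rank_sum_p(a, b, exact_max_n=0)
        assert (m1, m2) == ("exact", "asymptotic")
        assert p_asym == pytest.approx(p_exact, rel=0.10)


class TestCellLevelDe:
    def _two_group_ds(self, counts_a, counts_b):
        cells = [("cm", "s1", "female", "case")] * len(counts_a) + [
            ("cm", "s2", "female", "control")
        ] * len(counts_b)
        counts = [[c, 1] for c in counts_a + counts_b]
        ds = build_dataset(cells, counts)
        return normalize_counts(ds)

    def test_identical_groups_maximal_p_zero_lfc(self):
        ds = self._two_group_ds([1, 2, 3], [1, 2, 3])
        res = cell_level_de(ds, "SPEG", "cm", "case_female", "control_female")
        assert res.p_raw == 1.0
        assert res.avg_log2fc == pytest.approx(0.0)
        assert res.pct_a == res.pct_b == 1.0

    def test_avg_log2fc_antisymmetric(self, small_sc_dataset):
        ds = small_sc_dataset.dataset
        fwd = cell_level_de(ds, "SPEG", "cardiomyocyte", "case_female", "case_male")
        rev = cell_level_de(ds, "SPEG", "cardiomyocyte", "case_male", "case_female")
        assert fwd.avg_log2fc == pytest.approx(-rev.avg_log2fc)
        assert fwd.pct_a == rev.pct_b and fwd.pct_b == rev.pct_a
        assert fwd.p_raw == pytest.approx(rev.p_raw)

    def test_avg_log2fc_definition(self):
        a = np.array([1.0, 2.0])
        b = np.array([0.5, 0.2])
        expected = np.log2(np.expm1(a).mean() + 1) - np.log2(np.expm1(b).mean() + 1)
        assert average_log2_fold_change(a, b) == pytest.approx(expected)

    def test_empty_stratum_is_error(self):
        ds = self._two_group_ds([1, 2], [1, 2])
        with pytest.raises(DegenerateStatisticsError, match="case_male"):
            cell_level_de(ds, "SPEG", "cm", "case_male", "control_female")

    def test_bonferroni_family_is_types_times_pairs(self, small_sc_dataset):
        ds = small_sc_dataset.dataset
        de = cell_level_de_all(ds, "SPEG")
        n_types = len(de.attrs["expressed_cell_types"])
        assert de.attrs["n_comparisons"] == n_types * 6
        assert de.attrs["threshold"] == pytest.approx(0.05 / (n_types * 6))
        row = de.iloc[0]
        assert row.p_bonferroni == pytest.approx(
            min(1.0, row.p_raw * de.attrs["n_comparisons"])
        )


class TestCompositionCompare:
    def test_single_cell_type_share_is_unity_and_null(self):
        cells = []
        for g, (sex, dis) in {
            "s1": ("female", "case"), "s2": ("male", "case"),
            "s3": ("female", "control"), "s4": ("male", "control"),
            "s5": ("female", "case"), "s6": ("male", "case"),
            "s7": ("female", "control"), "s8": ("male", "control"),
        }.items():
            cells += [("cm", g, sex, dis)] * 5
        ds = build_dataset(cells, [[1, 1]] * len(cells))
        normalize_counts(ds)
        summ = summarize_samples(ds, "SPEG")
        assert (summ["pct_of_sample"] == 1.0).all()
        out = composition_compare(summ, "pct_of_sample")
        assert (out["p_adjusted"] == 1.0).all()

    def test_metric_names_validated(self, small_sc_dataset):
        summ = summarize_samples(small_sc_dataset.dataset, "SPEG")
        with pytest.raises(Exception, match="metric"):
            composition_compare(summ, "median_log2")

    def test_expression_compare_uses_median(self, small_sc_dataset):
        summ = summarize_samples(small_sc_dataset.dataset, "SPEG")
        out = expression_compare(summ)
        sub = summ.loc[summ.cell_type == "cardiomyocyte"]
        ref = tukey_pairwise(sub["median_log2"].to_numpy(), sub["group"].to_numpy())
        got = out.loc[out.cell_type == "cardiomyocyte", "p_adjusted"].to_numpy()
        np.testing.assert_allclose(got, ref["p_adjusted"].to_numpy())


class TestBulkTtest:
    def _tidy(self, contrasts):
        rows = []
        for name, (inf, mock) in contrasts.items():
            rows += [{"contrast": name, "condition": "infected", "value": v} for v in inf]
            rows += [{"contrast": name, "condition": "mock", "value": v} for v in mock]
        return pd.DataFrame(rows)

    def test_identical_arms_p_one(self):
        out = bulk_ttest(self._tidy({"cm_moi0.1": ([5, 5, 5], [5, 5, 5])}))
        assert out.loc[0, "p"] == 1.0

    def test_closed_form_pooled_t(self):
        out = bulk_ttest(self._tidy({"cm": ([10, 11, 12], [20, 21, 22])}))
        assert out.loc[0, "t"] == pytest.approx(-12.247, abs=1e-3)
        assert out.loc[0, "p"] == pytest.approx(2.55e-4, rel=0.01)

    def test_six_contrast_threshold(self):
        contrasts = {f"c{i}": ([1.0, 2, 3], [1.5, 2.5, 3.5]) for i in range(6)}
        out = bulk_ttest(self._tidy(contrasts), alpha=0.05)
        assert out.attrs["threshold"] == pytest.approx(0.008333, abs=1e-6)

    def test_too_few_replicates_is_error(self):
        with pytest.raises(DegenerateStatisticsError, match="replicates"):
            bulk_ttest(self._tidy({"cm": ([1.0], [2.0, 3.0])}))


class TestDatasetIo:
    def test_mtx_round_trip(self, tmp_path, small_sc_dataset):
        ds = small_sc_dataset.dataset
        save_dataset(
            ds, tmp_path / "c.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv"
        )
        back = load_dataset(
            tmp_path / "c.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv"
        )
        assert back.n_cells == ds.n_cells
        assert list(back.genes) == list(ds.genes)
        np.testing.assert_array_equal(
            np.asarray(back.adata.X.todense()), np.asarray(ds.adata.X.todense())
        )
        pd.testing.assert_series_equal(
            back.adata.obs["group"], ds.adata.obs["group"], check_categorical=False
        )

    def test_sample_in_two_groups_rejected(self):
        cells = [("cm", "s1", "female", "case"), ("cm", "s1", "male", "case")]
        with pytest.raises(DataError, match="more than one group"):
            build_dataset(cells, [[1, 1], [1, 1]])
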