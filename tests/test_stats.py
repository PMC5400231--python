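"""Burden counting and the group-comparison statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from rvburden import fixtures
from rvburden.genesets import top_k
from rvburden.stats import (
    DegenerateStatisticsError,
    bh_fdr,
    burden_counts,
    empirical_specificity,
    gene_count_table,
    rank_comparison,
    set_burden_from_table,
    total_adjusted_test,
    welch_one_sided,
    welch_one_sided_matrix,
    wilcoxon_one_sided,
)
from rvburden.types import (
    EffectRaw,
    GeneSet,
    GenomicInterval,
    Group,
    Subject,
    VariantAnnotation,
    VariantCall,
    Zygosity,
)

CASE_X = [12, 7, 11]
CTRL_Y = [3, 4, 4, 5, 8, 5]

DAMAGING_SCORES = {
    "sift": 0.01, "polyphen2": 0.99, "cadd_phred": 25.0, "mutation_taster": 0.9,
}


def _records_from_case_table():
    """Turn the bundled case variant list into (call, annotation) records;
    missense entries get scores passing the 4-of-7 rule."""
    records = []
    for row in fixtures.case_variant_table().itertuples(index=False):
        call = VariantCall(
            GenomicInterval(row.chrom, row.pos - 1, row.pos - 1 + len(row.ref)),
            row.ref,
            row.alt,
            row.case,
            Zygosity.HETEROZYGOUS,
        )
        effect = EffectRaw.MISSENSE if row.variant_class == "missense" else EffectRaw.STOP_GAIN
        scores = DAMAGING_SCORES if row.variant_class == "missense" else {}
        records.append(
            (call, VariantAnnotation(gene=row.gene, effect_raw=effect, scores=scores))
        )
    return records


class TestBurdenCounts:
    def test_case_counts_against_reference_table(self):
        """The case variant list recovers the published per-subject top-1000
        missense counts (12/7/11) and top-500 counts (8/4/5)."""
        records = _records_from_case_table()
        rl = fixtures.ranked_list_fixture(1000)
        counts1000 = burden_counts(records, top_k(rl, 1000), "damaging_missense")
        assert [counts1000[c] for c in fixtures.CASE_IDS] == [12, 7, 11]
        counts500 = burden_counts(records, top_k(rl, 500), "damaging_missense")
        assert [counts500.get(c, 0) for c in fixtures.CASE_IDS] == [8, 4, 5]

    def test_lof_counts_from_reference_table(self):
        records = _records_from_case_table()
        counts = burden_counts(records, top_k(fixtures.ranked_list_fixture(1000), 1000), "LOF")
        assert [counts.get(c, 0) for c in fixtures.CASE_IDS] == [1, 1, 0]

    def test_empty_records_give_zero_for_every_subject(self):
        subjects = [Subject("S1", Group.CASE), Subject("S2", Group.CONTROL)]
        counts = burden_counts([], GeneSet("g", frozenset({"A"})), "LOF", subjects=subjects)
        assert counts == {"S1": 0, "S2": 0}

    def test_duplicate_transcript_records_count_once(self):
        call = VariantCall(GenomicInterval("1", 99, 100), "A", "T", "S1", Zygosity.HETEROZYGOUS)
        ann = VariantAnnotation(gene="G1", effect_raw=EffectRaw.STOP_GAIN)
        counts = burden_counts([(call, ann), (call, ann)], GeneSet("g", frozenset({"G1"})), "LOF")
        assert counts == {"S1": 1}

    def test_homozygous_tabulated_separately(self):
        hom = VariantCall(GenomicInterval("1", 99, 100), "A", "T", "S1", Zygosity.HOMOZYGOUS)
        ann = VariantAnnotation(gene="G1", effect_raw=EffectRaw.STOP_GAIN)
        gs = GeneSet("g", frozenset({"G1"}))
        assert burden_counts([(hom, ann)], gs, "LOF") == {}
        assert burden_counts([(hom, ann)], gs, "LOF", include_homozygous=True) == {"S1": 1}

    def test_hemizygous_counted_by_default_but_switchable(self):
        """Deletion-region hemizygous calls count in any set holding their
        gene unless explicitly excluded."""
        hemi = VariantCall(
            GenomicInterval("22", 19_000_000, 19_000_001), "A", "T", "S1", Zygosity.HEMIZYGOUS
        )
        ann = VariantAnnotation(gene="DG1", effect_raw=EffectRaw.STOP_GAIN)
        gs = GeneSet("g", frozenset({"DG1"}))
        assert burden_counts([(hemi, ann)], gs, "LOF") == {"S1": 1}
        assert burden_counts([(hemi, ann)], gs, "LOF", include_hemizygous=False) == {}


class TestWelch:
    def test_reference_case_control_statistics(self):
        """Hand-evaluated Welch statistic/df for the headline comparison."""
        res = welch_one_sided(CASE_X, CTRL_Y, direction="observed")
        assert res.t == pytest.approx(3.072, abs=5e-4)
        assert res.df == pytest.approx(2.886, abs=5e-4)
        assert round(res.p_one_sided, 2) == 0.03

    def test_symmetric_groups_give_half(self):
        res = welch_one_sided([4, 5, 6], [4, 5, 6], direction="cases_greater")
        assert res.t == 0
        assert res.p_one_sided == 0.5

    def test_observed_direction_is_half_two_sided(self):
        res = welch_one_sided(CASE_X, CTRL_Y, direction="observed")
        two_sided = sps.ttest_ind(CASE_X, CTRL_Y, equal_var=False).pvalue
        assert res.p_one_sided == pytest.approx(two_sided / 2, rel=1e-12)

    def test_tail_complement(self):
        up = welch_one_sided(CASE_X, CTRL_Y, direction="cases_greater").p_one_sided
        down = welch_one_sided(CASE_X, CTRL_Y, direction="controls_greater").p_one_sided
        assert up + down == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_groups_flagged(self):
        with pytest.raises(DegenerateStatisticsError):
            welch_one_sided([2, 2, 2], [2, 2, 2])

    def test_matrix_path_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(6, size=(50, 3))
        Y = rng.poisson(4, size=(50, 6))
        ps = welch_one_sided_matrix(X, Y, direction="cases_greater")
        for i in range(50):
            assert ps[i] == pytest.approx(
                welch_one_sided(X[i], Y[i], direction="cases_greater").p_one_sided, rel=1e-10
            )


def _brute_force_wilcoxon(x, y, direction):
    """Enumerate every assignment of pooled midranks (independent oracle)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, n = len(x), len(pooled)
    w_obs = ranks[:nx].sum()
    ge = le = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if direction == "cases_greater":
        return ge / total
    return le / total


class TestWilcoxon:
    def test_top_ranks_probability(self):
        """Cases occupying the 3 top ranks of 9 distinct values: exactly one
        of C(9,3)=84 assignments is as extreme."""
        x, y = [7.0, 8.0, 9.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert wilcoxon_one_sided(x, y, "cases_greater") == pytest.approx(1 / 84)

    def test_all_tied_returns_half_by_convention(self):
        assert wilcoxon_one_sided([5, 5, 5], [5, 5, 5], "cases_greater") == 0.5

    def test_same_rejection_pattern_as_welch_on_reference_counts(self):
        p = wilcoxon_one_sided(CASE_X, CTRL_Y, "observed")
        assert p < 0.05  # agrees with the Welch rejection at alpha = 0.05

    def test_exact_enumeration_matches_brute_force(self):
        """Tie-aware exact p equals full enumeration for nx+ny <= 10."""
        rng = np.random.default_rng(12)
        for _ in range(40):
            nx = int(rng.integers(2, 5))
            ny = int(rng.integers(2, 11 - nx))
            x = rng.integers(0, 5, size=nx).astype(float)
            y = rng.integers(0, 5, size=ny).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            for direction in ("cases_greater", "controls_greater"):
                assert wilcoxon_one_sided(x, y, direction) == pytest.approx(
                    _brute_force_wilcoxon(x, y, direction)
                )


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_computation(self):
        qs = bh_fdr([0.03, 0.06, 0.07, 0.14, 0.29])
        assert qs == pytest.approx([0.11667, 0.11667, 0.11667, 0.175, 0.29], abs=5e-5)

    def test_permutation_invariance_and_dominates_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1, size=12)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        perm = rng.permutation(12)
        q_perm = bh_fdr(p[perm])
        assert q_perm == pytest.approx(q[perm])

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestTotalAdjusted:
    def test_reference_counts_remain_significant_after_adjustment(self):
        """Adjusting the target-set burden for each subject's genome-wide
        damaging-missense total keeps p below 0.05."""
        res = total_adjusted_test(
            CASE_X, CTRL_Y, [97, 98, 117], [102, 79, 95, 90, 82, 89], direction="observed"
        )
        assert res.p_one_sided < 0.05
        assert res.method == "total_adjusted_proportion_welch"

    def test_scale_invariance(self):
        a = total_adjusted_test(CASE_X, CTRL_Y, [97, 98, 117], [102, 79, 95, 90, 82, 89])
        doubled = total_adjusted_test(
            [2 * v for v in CASE_X],
            [2 * v for v in CTRL_Y],
            [194, 196, 234],
            [204, 158, 190, 180, 164, 178],
        )
        assert doubled.p_one_sided == pytest.approx(a.p_one_sided, rel=1e-12)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            total_adjusted_test([1, 1, 1], [1, 1, 1], [0, 1, 1], [1, 1, 1])

    def test_all_zero_set_counts_flagged_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            total_adjusted_test([0, 0, 0], [0, 0, 0], [10, 10, 10], [10, 10, 10])


class TestEmpiricalSpecificity:
    def test_extreme_observed_p(self):
        nulls = [0.2, 0.5, 0.9]
        assert empirical_specificity(0.1, nulls)[0] == 0.0
        assert empirical_specificity(1.0, nulls)[0] == 1.0

    def test_strictly_less_comparison(self):
        frac, _ = empirical_specificity(0.5, [0.5, 0.4, 0.6])
        assert frac == pytest.approx(1 / 3)


class TestGeneCountTable:
    def test_table_sums_match_direct_burden_counts(self, small_bundle):
        from rvburden.filters import apply_filters

        kept, _ = apply_filters(small_bundle.records, small_bundle.subjects)
        table = gene_count_table(kept, small_bundle.subjects, "damaging_missense")
        direct = burden_counts(
            kept, small_bundle.target_set, "damaging_missense", subjects=small_bundle.subjects
        )
        via_table = set_burden_from_table(table, small_bundle.target_set)
        for sid, n in direct.items():
            assert via_table[sid] == n


class TestRankComparison:
    def test_identical_rank_lists(self):
        assert rank_comparison([1, 2, 3], [1, 2, 3])[2] == 0.5

    def test_means_reported(self):
        mc, mn, _ = rank_comparison([1, 2, 3], [100, 200, 300])
        assert (mc, mn) == (2.0, 200.0)

    def test_reference_pooled_case_ranks(self):
        """Pooled missense ranks of the case variant list average ~453."""
        missense = fixtures.case_variant_table().query("variant_class == 'missense'")
        assert missense["rank"].mean() == pytest.approx(453, abs=1)
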