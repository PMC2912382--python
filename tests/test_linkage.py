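import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sporescan import (PairCategoryCounts, SegmentMatrix, categorize_pair,
                       chi_square_pair, classify_dependency, expected_counts,
                       intrachromosomal_distance_scan, nine_category_table,
                       permutation_fdr, scan_pairs, scan_with_fdr)
from sporescan.linkage import _pair_tables, _permuted_scores

from helpers import (brute_force_chi_square, brute_force_expected, iid_matrix,
                     truth_matrix)


class TestCategorize:
    def test_enumeration(self):
        counts = categorize_pair(np.array([1, 1, 0, 0]),
                                 np.array([1, 0, 1, 0]))
        assert (counts.n11, counts.n10, counts.n01, counts.n00) == (1, 1, 1, 1)

    def test_aneuploid_spores_excluded(self):
        counts = categorize_pair(np.array([1, 2, 0]), np.array([1, 1, 0]))
        assert (counts.n11, counts.n10, counts.n01, counts.n00) == (1, 0, 0, 1)
        assert counts.n_informative == 2

    def test_missing_scores_excluded(self):
        counts = categorize_pair(np.array([1, -1, 0]), np.array([1, 1, 0]))
        assert counts.n_informative == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            categorize_pair(np.array([1, 0]), np.array([1]))

    def test_counts_sum_to_non_aneuploid_spores(self):
        rng = np.random.default_rng(4)
        a = rng.choice([0, 1, 2], size=8, p=[0.4, 0.4, 0.2])
        b = rng.choice([0, 1, 2], size=8, p=[0.4, 0.4, 0.2])
        counts = categorize_pair(a, b)
        expected_n = int(np.sum(np.isin(a, (0, 1)) & np.isin(b, (0, 1))))
        assert counts.n_informative == expected_n


class TestExpectedCounts:
    def test_published_worked_example(self):
        # 20/106 and 50/106 inheritance: E(both) = (20/106)(50/106)*106
        counts = PairCategoryCounts(n11=0, n10=20, n01=50, n00=36)
        e = expected_counts(counts, n_total=106)
        assert e[0] == pytest.approx(9.434, abs=1e-3)

    def test_zero_marginal_zeroes_expectations(self):
        counts = PairCategoryCounts(n11=0, n10=0, n01=10, n00=10)
        e = expected_counts(counts)
        assert e[0] == 0 and e[1] == 0

    def test_balanced_marginals_quarter_each(self):
        counts = PairCategoryCounts(n11=5, n10=5, n01=5, n00=5)
        assert np.allclose(expected_counts(counts), 5.0)

    def test_expectations_sum_to_n(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(0, 30, size=4)
            if n.sum() == 0:
                continue
            counts = PairCategoryCounts(*map(int, n))
            assert np.isclose(expected_counts(counts).sum(),
                              counts.n_informative)


class TestChiSquare:
    def test_observed_equals_expected_gives_zero(self):
        counts = PairCategoryCounts(n11=5, n10=5, n01=5, n00=5)
        r = chi_square_pair(counts)
        assert r.chi_square == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_perfect_linkage_hand_expansion(self):
        r = chi_square_pair(PairCategoryCounts(10, 0, 0, 10))
        assert r.chi_square == pytest.approx(20.0)

    def test_table_value_three_df(self):
        # chi-square of 11.345 at 3 df sits at p = 0.01
        assert stats.chi2.sf(11.345, 3) == pytest.approx(0.01, rel=1e-3)
        r = chi_square_pair(PairCategoryCounts(10, 0, 0, 10))
        assert r.p_value == pytest.approx(stats.chi2.sf(20.0, 3))
        assert r.p_value_df1 == pytest.approx(stats.chi2.sf(20.0, 1))

    @settings(derandomize=True, max_examples=300)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_brute_force_oracle(self, cells):
        if sum(cells) == 0:
            return
        counts = PairCategoryCounts(*cells)
        r = chi_square_pair(counts)
        assert np.allclose(r.expected, brute_force_expected(counts),
                           atol=1e-12)
        oracle = brute_force_chi_square(counts)
        if np.isinf(oracle):
            assert np.isinf(r.chi_square)
        else:
            assert r.chi_square == pytest.approx(oracle, abs=1e-9)

    def test_cell_conservation(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            cells = rng.integers(0, 40, size=4)
            if cells.sum() == 0:
                continue
            counts = PairCategoryCounts(*map(int, cells))
            r = chi_square_pair(counts)
            assert np.isclose(r.expected.sum(), counts.n_informative)


class TestClassify:
    @pytest.mark.parametrize("cells,expected", [
        ((30, 0, 0, 40), "two_way"),
        ((30, 12, 0, 40), "one_way"),
        ((30, 0, 12, 40), "one_way"),
        ((25, 25, 25, 25), "none"),
    ])
    def test_dependency_classes(self, cells, expected):
        assert classify_dependency(PairCategoryCounts(*cells)) == expected

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            classify_dependency(PairCategoryCounts(0, 0, 0, 0))


class TestScan:
    def test_interchromosomal_combinatorics(self):
        m = iid_matrix(20, 6, seed=1, n_chrom=3)   # 3 chroms x 2 segments
        results = scan_pairs(m, interchromosomal_only=True)
        assert len(results) == 12                  # 4 + 4 + 4 cross pairs

    def test_single_chromosome_scan_empty(self):
        m = iid_matrix(20, 5, seed=2, n_chrom=1)
        assert len(scan_pairs(m, interchromosomal_only=True)) == 0

    def test_vectorized_tables_match_categorize(self):
        m = iid_matrix(30, 8, seed=3)
        m.scores[m.scores == 1] = np.where(
            np.random.default_rng(0).random(np.sum(m.scores == 1)) < 0.1,
            2, 1).astype(np.int8)
        t = _pair_tables(m.scores)
        for i in range(8):
            for j in range(i + 1, 8):
                c = categorize_pair(m.scores[:, i], m.scores[:, j])
                assert t["n11"][i, j] == c.n11
                assert t["n10"][i, j] == c.n10
                assert t["n01"][i, j] == c.n01
                assert t["n00"][i, j] == c.n00

    def test_scan_statistics_match_single_pair_path(self):
        m = iid_matrix(40, 6, seed=5)
        results = scan_pairs(m)
        for row in results.itertuples(index=False):
            c = categorize_pair(m.scores[:, row.idx_a], m.scores[:, row.idx_b])
            r = chi_square_pair(c)
            assert row.chi_square == pytest.approx(r.chi_square, abs=1e-9)

    def test_reciprocal_genomes_give_identical_statistics(
            self, noiseless_matrices):
        # scanning the par matrix relabels categories (11<->00, 10<->01)
        # and must give the same statistic wherever no spore is aneuploid
        # or missing; with per-genome grids, compare via relabeled scores
        cer = noiseless_matrices["cer"]
        flipped = SegmentMatrix(
            genome="par", segments=cer.segments,
            scores=np.where(np.isin(cer.scores, (0, 1)),
                            1 - cer.scores, cer.scores).astype(np.int8),
            spore_ids=cer.spore_ids)
        a = scan_pairs(cer)
        b = scan_pairs(flipped)
        assert np.allclose(a["chi_square"], b["chi_square"], atol=1e-9)


class TestPermutationFDR:
    def test_shuffle_preserves_marginals(self):
        m = iid_matrix(50, 10, seed=8)
        m.scores[0, :] = 2
        m.scores[1, :] = -1
        shuffled = _permuted_scores(m.scores, np.random.default_rng(0))
        for j in range(10):
            assert (np.bincount(shuffled[:, j] + 1, minlength=4).tolist()
                    == np.bincount(m.scores[:, j] + 1, minlength=4).tolist())

    def test_duplicated_segment_detected(self):
        # a segment vector duplicated on another chromosome is perfectly
        # linked with itself and must reach FDR < 0.01
        rng = np.random.default_rng(21)
        m = iid_matrix(60, 20, seed=21, n_chrom=10)
        dup_src, dup_dst = 0, 3     # different chromosomes
        m.scores[:, dup_dst] = m.scores[:, dup_src]
        results = scan_with_fdr(m, n_perm=200, seed=5)
        pair = results[((results["idx_a"] == dup_src)
                        & (results["idx_b"] == dup_dst))
                       | ((results["idx_a"] == dup_dst)
                          & (results["idx_b"] == dup_src))]
        assert len(pair) == 1
        assert pair["fdr"].iloc[0] < 0.01
        assert pair["chi_square"].iloc[0] == results["chi_square"].max()

    def test_null_matrix_fdr_calibration(self):
        # i.i.d. fair-coin segments: almost no pair may reach FDR < 0.01
        n_sig = n_pairs = 0
        for seed in range(5):
            m = iid_matrix(80, 24, seed=100 + seed, n_chrom=12)
            results = scan_with_fdr(m, n_perm=100, seed=seed)
            n_sig += int((results["fdr"] < 0.01).sum())
            n_pairs += len(results)
        assert n_sig / n_pairs <= 0.02

    def test_fdr_deterministic_given_seed(self):
        m = iid_matrix(40, 10, seed=3, n_chrom=5)
        r = scan_pairs(m)
        f1 = permutation_fdr(r, m, n_perm=50, seed=9)
        f2 = permutation_fdr(r, m, n_perm=50, seed=9)
        assert np.array_equal(f1, f2, equal_nan=True)


class TestNineCategories:
    def test_tally_includes_aneuploid_cells(self):
        a = np.array([1, 1, 0, 2, 2])
        b = np.array([1, 0, 0, 1, 2])
        table = nine_category_table(a, b)
        assert table.loc["a=1", "b=1"] == 1
        assert table.loc["a=2", "b=1"] == 1
        assert table.loc["a=2", "b=2"] == 1
        assert table.to_numpy().sum() == 5


class TestIntrachromosomalScan:
    def test_no_crossovers_all_pairs_perfectly_linked(self):
        # whole-chromosome co-inheritance: same-chromosome segments always
        # share their origin, so both mixed cells stay empty
        rng = np.random.default_rng(2)
        origins = rng.integers(0, 2, size=(50, 4))
        scores = np.repeat(origins, 3, axis=1).astype(np.int8)  # 3 seg/chrom
        segments = pd.DataFrame({
            "chrom": np.repeat(np.arange(1, 5), 3),
            "start": np.tile([0.0, 1e5, 2e5], 4),
            "end": np.tile([1e5, 2e5, 3e5], 4)})
        m = SegmentMatrix(genome="cer", segments=segments, scores=scores,
                          spore_ids=[f"s{i}" for i in range(50)])
        results = scan_pairs(m, interchromosomal_only=False)
        same = results[results["chrom_a"] == results["chrom_b"]]
        assert (same["n10"] == 0).all() and (same["n01"] == 0).all()

    def test_linkage_decays_with_distance(self):
        # low recombination: adjacent segments are more tightly linked
        # than distant ones on the same chromosome
        from sporescan import SimParams, simulate_gamete
        lengths = {1: 1_000_000}
        params = SimParams(n_spores=1, crossover_mean_per_genome=6.0,
                           aneuploidy_prob_per_chromosome=0.0,
                           chromosome_lengths=lengths)
        rng = np.random.default_rng(31)
        gametes = [simulate_gamete(params, rng) for _ in range(120)]
        m = truth_matrix(gametes, lengths, segments_per_chrom=15)
        table, _ = intrachromosomal_distance_scan(m, n_perm=30, seed=1)
        near = table[table["distance_bp"] <= 150_000]["chi_square"]
        far = table[table["distance_bp"] >= 500_000]["chi_square"]
        assert near.median() > far.median()

    def test_linkage_horizon_shrinks_with_recombination(self):
        from sporescan import SimParams, simulate_gamete
        lengths = {1: 1_000_000}
        horizons = {}
        for mean_xo in (3.0, 12.0):
            params = SimParams(n_spores=1,
                               crossover_mean_per_genome=mean_xo,
                               aneuploidy_prob_per_chromosome=0.0,
                               chromosome_lengths=lengths)
            vals = []
            for seed in range(10):
                rng = np.random.default_rng(1000 + seed)
                gametes = [simulate_gamete(params, rng) for _ in range(100)]
                m = truth_matrix(gametes, lengths, segments_per_chrom=12)
                _, min_unlinked = intrachromosomal_distance_scan(
                    m, fdr_threshold=0.01, n_perm=50, seed=seed)
                vals.append(min_unlinked)
            horizons[mean_xo] = np.median(vals)
        assert horizons[12.0] <= horizons[3.0]
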