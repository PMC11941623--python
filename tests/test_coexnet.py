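import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coexdiff as cd
from coexdiff.coexnet import _mi_from_table, pairwise_mi

LN2 = np.log(2.0)


class TestDiscretize:
    def test_two_bin_assignment(self):
        out = cd.discretize_equal_frequency(np.array([[1.0, 2.0, 3.0, 4.0]]), n_bins=2)
        np.testing.assert_array_equal(out.bins[0], [0, 0, 1, 1])

    def test_constant_gene_collapses_to_single_bin(self):
        out = cd.discretize_equal_frequency(np.array([[7.0, 7.0, 7.0, 7.0]]), n_bins=2)
        np.testing.assert_array_equal(out.bins[0], [0, 0, 0, 0])

    def test_stable_tie_rule_keeps_balanced_occupancy(self):
        out = cd.discretize_equal_frequency(np.array([[1.0, 1.0, 2.0, 2.0]]), n_bins=2)
        counts = np.bincount(out.bins[0], minlength=2)
        np.testing.assert_array_equal(counts, [2, 2])

    def test_default_bin_count_is_sqrt_n(self):
        expr = np.random.default_rng(0).normal(size=(3, 174))
        assert cd.discretize_equal_frequency(expr).n_bins == 13

    def test_occupancies_near_equal_without_ties(self):
        expr = np.random.default_rng(1).normal(size=(20, 47))
        out = cd.discretize_equal_frequency(expr)
        for row in out.bins:
            occ = np.bincount(row, minlength=out.n_bins)
            assert occ.max() - occ.min() <= 1


class TestMutualInformation:
    def test_perfect_dependence_on_two_bins(self):
        x = [0, 1] * 5
        assert cd.mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_margin_gives_zero(self):
        assert cd.mutual_information([0, 1, 0, 1], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_hand_evaluated_table(self):
        # joint [[2,1],[1,2]], n=6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 1, 1, 0]
        expected = (2 / 3) * np.log2(4 / 3) + (1 / 3) * np.log2(2 / 3)
        assert cd.mutual_information(x, y) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cd.mutual_information([0, 1], [0, 1, 0])

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=40))
    def test_symmetry_and_nonnegativity(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        mxy = cd.mutual_information(x, y, n_bins=4)
        assert mxy == pytest.approx(cd.mutual_information(y, x, n_bins=4), abs=1e-12)
        assert mxy >= 0.0

    def test_self_information_dominates(self):
        # data-processing sanity: MI(x, x) >= MI(x, y) on the same binning
        rng = np.random.default_rng(2)
        binned = cd.discretize_equal_frequency(rng.normal(size=(10, 60)))
        x = binned.bins[0]
        mxx = cd.mutual_information(x, x, binned.n_bins)
        for y in binned.bins[1:]:
            assert mxx >= cd.mutual_information(x, y, binned.n_bins) - 1e-12


class TestPairwiseMI:
    def test_pair_count_and_agreement_with_scalar_path(self):
        rng = np.random.default_rng(3)
        binned = cd.discretize_equal_frequency(rng.normal(size=(4, 30)))
        mi = pairwise_mi(binned)
        assert mi.size == 6
        from itertools import combinations

        naive = [
            cd.mutual_information(binned.bins[i], binned.bins[j], binned.n_bins)
            for i, j in combinations(range(4), 2)
        ]
        np.testing.assert_allclose(mi, naive, atol=1e-12)

    def test_miller_madow_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        binned = cd.discretize_equal_frequency(rng.normal(size=(5, 36)))
        mi = pairwise_mi(binned, miller_madow=True)
        from itertools import combinations

        naive = [
            cd.mutual_information(binned.bins[i], binned.bins[j], binned.n_bins, miller_madow=True)
            for i, j in combinations(range(5), 2)
        ]
        np.testing.assert_allclose(mi, naive, atol=1e-12)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=(6, 40))
        perm = rng.permutation(40)
        a = pairwise_mi(cd.discretize_equal_frequency(expr))
        b = pairwise_mi(cd.discretize_equal_frequency(expr[:, perm]))
        np.testing.assert_allclose(np.sort(a), np.sort(b), atol=1e-12)

    def test_duplicated_gene_rows_maximize_mi(self):
        rng = np.random.default_rng(5)
        expr = rng.normal(size=(5, 50))
        expr[1] = expr[0]
        binned = cd.discretize_equal_frequency(expr)
        mi = pairwise_mi(binned)
        # condensed index of pair (0, 1) is 0
        assert mi[0] == pytest.approx(mi.max())


class TestSignificance:
    def test_null_mi_gives_p_one(self):
        assert cd.mi_significance(0.0, 100) == pytest.approx(1.0)

    def test_chi2_oracle(self):
        from scipy import stats

        mi = (2 / 3) * np.log2(4 / 3) + (1 / 3) * np.log2(2 / 3)
        p = cd.mi_significance(mi, 100, 2, 2)
        g = 2 * 100 * LN2 * mi
        assert g == pytest.approx(11.33, abs=0.01)
        assert p == pytest.approx(stats.chi2.sf(g, 1), rel=1e-12)
        assert p == pytest.approx(7.6e-4, rel=0.02)

    def test_monotone_decreasing_and_extreme_tail(self):
        # at n=174, r=c=13: p strictly decreasing in MI, tiny for strong MI
        mis = np.linspace(0.01, 3.5, 50)
        ps = cd.mi_significance(mis, 174, 13, 13)
        assert np.all(np.diff(ps) <= 0)
        inside = ps < 1.0  # strictly decreasing once below the saturation at 1
        assert np.all(np.diff(ps[inside]) < 0)
        assert ps[-1] < 1e-30

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.mi_significance(0.1, 0)

    def test_g_identity_against_scipy(self):
        # 2*n*ln2*I equals the likelihood-ratio G statistic of the table
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(6)
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4)).astype(float)
            mi = _mi_from_table(table)
            g_direct = chi2_contingency(table, lambda_="log-likelihood", correction=False)[0]
            assert 2 * table.sum() * LN2 * mi == pytest.approx(g_direct, rel=1e-9)


class TestThreshold:
    def test_exact_count_at_99th_percentile(self):
        rng = np.random.default_rng(7)
        g = 46  # 1035 pairs
        mi = rng.permutation(np.linspace(0.001, 1.0, g * (g - 1) // 2))
        net = cd.threshold_at_percentile([f"n{i}" for i in range(g)], mi, 99.0)
        # ceil(1% of 1035) values sit at or above the interpolated percentile
        assert net.n_edges == 11
        assert (net.edges["mi_bits"] >= net.threshold_value).all()

    def test_all_equal_values_keep_every_edge(self):
        mi = np.full(6, 0.25)
        net = cd.threshold_at_percentile(["a", "b", "c", "d"], mi, 99.0)
        assert net.n_edges == 6

    def test_module_recovery(self):
        hits = []
        for seed in range(2):
            p = cd.SimParams(
                n_genes=200, n_modules=5, module_size=20, n_early=50, n_late=50,
                factor_loading=0.8, de_fraction=0.0, n_true_terms=0,
                n_decoy_terms=0, n_perturbed_sets=0, seed=seed,
            )
            truth = cd.simulate_truth(p)
            design = cd.simulate_design(p)
            cm = cd.CountMatrix(cd.simulate_counts(truth, design, p), design)
            logc = cd.cpm(cm, cd.compute_tmm_factors(cm), log=True)
            net = cd.infer_network(logc, percentile=99.0)
            intra = np.mean(
                [
                    truth.module_of[a] == truth.module_of[b] != "background"
                    for a, b in zip(net.edges["gene_a"], net.edges["gene_b"])
                ]
            )
            hits.append(intra)
        assert np.mean(hits) >= 0.8
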