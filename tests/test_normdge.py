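import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import coexdiff as cd
from coexdiff.normdge import _exact_nb_pvalue

from conftest import nb_counts


def make_cm(array, design=None, genes=None):
    arr = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = design.sample_id if design else [f"s{i}" for i in range(arr.shape[1])]
    return cd.CountMatrix(pd.DataFrame(arr, index=genes, columns=cols), design)


class TestFilterLowExpression:
    def test_all_zero_gene_removed_and_boundary_inclusive(self):
        # library sizes 100 -> CPM = 1e4 * count
        cm = make_cm([[0, 0, 0], [1, 0, 0], [1, 1, 0], [98, 99, 100]])
        kept = cd.filter_low_expression(cm, min_cpm=1.0, min_samples=2)
        assert kept.genes == ["g2", "g3"]

    def test_five_gene_toy_matrix(self):
        # columns sum to 1000: CPM = 1000 * count; threshold CPM >= 2000 in >= 2 samples
        counts = np.array(
            [
                [5, 5, 5],     # CPM 5000 everywhere       -> kept
                [2, 2, 0],     # CPM 2000 in two samples   -> kept (boundary)
                [3, 0, 0],     # high in one sample only   -> dropped
                [1, 1, 1],     # CPM 1000 everywhere       -> dropped
                [989, 992, 994],
            ]
        )
        cm = make_cm(counts)
        kept = cd.filter_low_expression(cm, min_cpm=2000.0, min_samples=2)
        assert kept.genes == ["g0", "g1", "g4"]

    def test_empty_result_warns(self):
        cm = make_cm([[1, 1], [1, 1]])
        with pytest.warns(UserWarning, match="every gene"):
            cd.filter_low_expression(cm, min_cpm=1e9, min_samples=1)


def naive_tmm_factor(yk, yr, trim_m=0.30, trim_a=0.05):
    """Literal transcription of the trimmed weighted-mean formula, kept
    independent of the implementation (explicit rank loops)."""
    nk, nr = yk.sum(), yr.sum()
    both = (yk > 0) & (yr > 0)
    yk, yr = yk[both].astype(float), yr[both].astype(float)
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    n = m.size
    keep = np.ones(n, dtype=bool)
    for values, trim in ((m, trim_m), (a, trim_a)):
        lo = int(np.floor(n * trim)) + 1
        hi = n + 1 - lo
        ranks = np.empty(n, int)
        ranks[np.argsort(values, kind="stable")] = np.arange(1, n + 1)
        keep &= (ranks >= lo) & (ranks <= hi)
    w = 1.0 / ((nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep]))
    return 2.0 ** (np.sum(w * m[keep]) / np.sum(w))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80])
        cm = make_cm(np.column_stack([col, col]))
        f = cd.compute_tmm_factors(cm)
        assert np.allclose(f.tmm_factor, 1.0)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        col = np.array([10, 50, 200, 5, 80])
        cm = make_cm(np.column_stack([col, 3 * col]))
        f = cd.compute_tmm_factors(cm)
        assert np.allclose(f.tmm_factor, 1.0)

    def test_eight_gene_fixture_matches_hand_formula(self):
        rng = np.random.default_rng(0)
        ya = rng.integers(20, 2000, size=8)
        yb = ya.copy()
        yb[0] *= 40  # one inflated gene that trimming must discard
        cm = make_cm(np.column_stack([ya, yb]))
        f = cd.compute_tmm_factors(cm)
        ref = cm.samples.index(f.reference_sample)
        other = 1 - ref
        cols = cm.counts.to_numpy()
        expected = naive_tmm_factor(cols[:, other], cols[:, ref])
        # implementation recentres to geometric mean 1: compare factor ratios
        got_ratio = f.tmm_factor.iloc[other] / f.tmm_factor.iloc[ref]
        assert got_ratio == pytest.approx(expected, rel=1e-12)

    def test_matches_edgeR_oracle(self, tmp_path):
        # independent cross-check against the Bioconductor implementation
        import subprocess

        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 5 / (5 + rng.uniform(20, 800, size=(300, 6))))
        cm = make_cm(counts)
        cm.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- read.delim('{tmp_path}/counts.tsv', row.names=1)\n"
            "f <- calcNormFactors(as.matrix(x), method='TMM')\n"
            f"write.table(data.frame(f=f), '{tmp_path}/f.tsv', sep='\\t', row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_factors = pd.read_csv(tmp_path / "f.tsv", sep="\t")["f"].to_numpy()
        f = cd.compute_tmm_factors(cm)
        np.testing.assert_allclose(f.tmm_factor.to_numpy(), r_factors, rtol=1e-8)


class TestCPM:
    def test_definitional_and_proportional(self, balanced_design):
        cm = make_cm(np.full((1, 2), 100))
        f = cd.NormalizationFactors(
            library_size=pd.Series([1e6, 1e6], index=cm.samples),
            tmm_factor=pd.Series([1.0, 2.0], index=cm.samples),
            reference_sample="s0",
        )
        vals = cd.cpm(cm, f)
        assert vals.iloc[0, 0] == pytest.approx(100.0)
        assert vals.iloc[0, 1] == pytest.approx(50.0)  # doubled factor halves CPM

    def test_log_cpm_finite_at_zero(self):
        cm = make_cm([[0, 5], [100, 100]])
        out = cd.cpm(cm, None, log=True)
        assert np.isfinite(out.to_numpy()).all()


class TestDispersion:
    def test_poisson_counts_give_near_zero(self, balanced_design):
        rng = np.random.default_rng(0)
        mu = rng.uniform(20, 500, size=2000)
        counts = nb_counts(rng, mu[:, None], 0.0, (2000, 50))
        cm = make_cm(counts, balanced_design)
        phi = cd.estimate_common_dispersion(cm, cd.compute_tmm_factors(cm))
        assert phi <= 0.02

    def test_nb_dispersion_recovered(self, balanced_design):
        rng = np.random.default_rng(1)
        mu = rng.uniform(50, 500, size=2000)
        counts = nb_counts(rng, mu[:, None], 0.2, (2000, 50))
        cm = make_cm(counts, balanced_design)
        phi = cd.estimate_common_dispersion(cm, cd.compute_tmm_factors(cm))
        assert 0.15 <= phi <= 0.25

    def test_constant_counts_floor_at_zero(self, balanced_design):
        cm = make_cm(np.full((10, 50), 7), balanced_design)
        phi = cd.estimate_common_dispersion(cm, cd.compute_tmm_factors(cm))
        assert phi == 0.0


class TestExactTest:
    def test_symmetric_gene_is_null(self):
        design = cd.assign_cohorts([60, 60, 80, 80])
        cm = make_cm([[5, 7, 7, 5], [100, 100, 100, 100]], design)
        f = cd.compute_tmm_factors(cm)
        table = cd.exact_test(cm, f, 0.0)
        assert table.loc["g0", "logFC"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["g0", "PValue"] == pytest.approx(1.0)

    def test_degenerates_to_two_sided_binomial(self):
        # phi=0, equal libraries, one sample per group, counts (3, 7):
        # conditional law is Binomial(10, 1/2); minimum-likelihood two-sided
        # p = P(k not in {4,5,6}) = 352/1024
        assert _exact_nb_pvalue(3, 7, 1, 1, 0.0) == pytest.approx(352 / 1024, rel=1e-9)

    def test_negative_dispersion_rejected(self, balanced_design):
        cm = make_cm(np.ones((2, 50), dtype=int), balanced_design)
        with pytest.raises(ValueError):
            cd.exact_test(cm, cd.compute_tmm_factors(cm), -0.1)

    def test_planted_de_recovery(self):
        p = cd.SimParams(
            n_genes=500, n_modules=0, module_size=0, factor_loading=0.0,
            dispersion=0.1, de_fraction=0.1, de_log2fc=2.0,
            libsize_range=(2e5, 4e5),
            n_true_terms=0, n_decoy_terms=0, n_perturbed_sets=0, seed=21,
        )
        truth = cd.simulate_truth(p)
        design = cd.simulate_design(p)
        cm = cd.CountMatrix(cd.simulate_counts(truth, design, p), design)
        f = cd.compute_tmm_factors(cm)
        table = cd.exact_test(cm, f, cd.estimate_common_dispersion(cm, f))
        sens = (table.loc[sorted(truth.de_genes), "FDR"] < 0.05).mean()
        assert sens >= 0.8


class TestBHAdjust:
    def test_examples(self):
        assert cd.bh_adjust([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(cd.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_monotone_on_sorted_input(self):
        q = cd.bh_adjust(np.linspace(0.001, 0.9, 25))
        assert np.all(np.diff(q) >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cd.bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(cd.bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    @given(st.permutations(list(range(12))))
    def test_permutation_equivariance(self, perm):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=12)
        perm = np.asarray(perm)
        np.testing.assert_allclose(cd.bh_adjust(p)[perm], cd.bh_adjust(p[perm]))
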