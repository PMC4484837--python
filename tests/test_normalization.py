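import numpy as np
import pytest

import _oracles as oracles
from normrank.counts_io import CountMatrix
from normrank.normalization import (
    METHODS,
    NormalizationError,
    compute_factors,
    median_ratio_factors,
    normalize_counts,
    poissonseq_factors,
    quantile_factors,
    raw_factors,
    tmm_factors,
    uq_factors,
)

from conftest import random_count_matrix


def geomean(x):
    return np.exp(np.mean(np.log(x)))


class TestHandExamples:
    def test_tmm_identical_samples_is_unit(self, identical_samples_cm):
        sf = tmm_factors(identical_samples_cm)
        np.testing.assert_allclose(sf.factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(sf.divisors, 1.0, atol=1e-12)

    def test_tmm_pure_depth_difference_cancels(self, rng):
        base = rng.integers(10, 500, size=(40, 1))
        counts = np.hstack([base, 2 * base, base])
        cm = CountMatrix(counts, [f"g{i}" for i in range(40)], ["r", "j", "k"])
        sf = tmm_factors(cm, reference="r")
        # doubling every count only doubles the library size: M values all 0
        np.testing.assert_allclose(sf.factors, 1.0, atol=1e-12)

    def test_uq_constant_sample_factor_is_one_over_g(self):
        counts = np.full((8, 2), 7)
        cm = CountMatrix(counts, [f"g{i}" for i in range(8)], ["a", "b"])
        np.testing.assert_allclose(uq_factors(cm).factors, 1 / 8)

    def test_uq_all_zero_gene_is_ignored(self, rng):
        cm = random_count_matrix(rng, n_genes=30, n_samples=3)
        with_zero = CountMatrix(
            np.vstack([cm.counts, np.zeros((1, 3), dtype=int)]),
            cm.gene_ids + ["zero"],
            cm.sample_ids,
        )
        np.testing.assert_allclose(
            uq_factors(cm).factors, uq_factors(with_zero).factors
        )

    def test_median_ratio_fourfold_sample(self):
        a = np.array([3, 11, 50, 7])
        cm = CountMatrix(
            np.column_stack([a, 4 * a]), [f"g{i}" for i in range(4)], ["a", "b"]
        )
        sf = median_ratio_factors(cm)
        np.testing.assert_allclose(sf.factors, [0.5, 2.0])
        np.testing.assert_allclose(sf.divisors, [0.5, 2.0])

    def test_quantile_two_decade_spread(self):
        # upper quartiles 10 and 1000 -> factors 10^(1-2) and 10^(3-2)
        counts = np.column_stack([np.full(9, 10), np.full(9, 1000)])
        cm = CountMatrix(counts, [f"g{i}" for i in range(9)], ["a", "b"])
        np.testing.assert_allclose(quantile_factors(cm).factors, [0.1, 10.0])

    def test_poissonseq_identical_samples(self, identical_samples_cm):
        sf, internals = poissonseq_factors(identical_samples_cm, return_internals=True)
        m = identical_samples_cm.n_samples
        np.testing.assert_allclose(internals.tc_factors, 1 / m)
        np.testing.assert_allclose(sf.factors, 1 / m)
        np.testing.assert_allclose(sf.divisors, 1.0, atol=1e-12)
        np.testing.assert_allclose(internals.gof, 0.0, atol=1e-12)

    def test_raw_divisors_all_one(self, small_cm):
        sf = raw_factors(small_cm)
        np.testing.assert_array_equal(sf.divisors, 1.0)
        np.testing.assert_array_equal(normalize_counts(small_cm, sf), small_cm.counts)

    def test_identical_samples_unit_divisors_everywhere(self, identical_samples_cm):
        for method in ("UQ", "DES", "EBS"):
            sf = compute_factors(identical_samples_cm, method)
            np.testing.assert_allclose(sf.divisors, 1.0, atol=1e-12, err_msg=method)


class TestOracleEquivalence:
    """Factors must match explicit-loop evaluations of their formulas."""

    @pytest.mark.parametrize("trial", range(20))
    def test_all_methods_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        cm = random_count_matrix(rng, n_genes=50, n_samples=4, low=1, high=300)
        counts = cm.counts

        sf = tmm_factors(cm)
        r = cm.sample_ids.index(sf.reference_sample)
        expected = [2.0 ** oracles.tmm_log2_factor(counts, j, r) for j in range(4)]
        np.testing.assert_allclose(sf.factors, expected, atol=1e-10, rtol=0)

        des = median_ratio_factors(cm)
        expected = [oracles.median_ratio_factor(counts, j) for j in range(4)]
        np.testing.assert_allclose(des.factors, expected, atol=1e-10, rtol=0)

        ebs = quantile_factors(cm)
        expected = [oracles.quantile_factor(counts, j) for j in range(4)]
        np.testing.assert_allclose(ebs.factors, expected, atol=1e-10, rtol=0)

        ps, internals = poissonseq_factors(cm, return_internals=True)
        expected, selected = oracles.poissonseq_factors(counts)
        np.testing.assert_allclose(ps.factors, expected, atol=1e-10, rtol=0)
        assert internals.selected_genes == [cm.gene_ids[g] for g in selected]


@pytest.fixture(scope="module")
def r_factors(tmp_path_factory):
    """TMM and median-of-ratios factors recomputed by edgeR / DESeq2 (Rscript)."""
    import subprocess

    rng = np.random.default_rng(77)
    counts = rng.integers(1, 800, size=(120, 5))
    tmp = tmp_path_factory.mktemp("rcheck")
    np.savetxt(tmp / "counts.tsv", counts, fmt="%d", delimiter="\t")
    script = tmp / "check.R"
    script.write_text(
        f"""
        counts <- as.matrix(read.table('{tmp / "counts.tsv"}', sep='\\t'))
        suppressMessages(library(edgeR))
        tmm <- calcNormFactors(counts, method='TMM')
        des <- DESeq2::estimateSizeFactorsForMatrix(counts)
        write(format(tmm, digits=15), '{tmp / "tmm.txt"}', ncolumns=1)
        write(format(des, digits=15), '{tmp / "des.txt"}', ncolumns=1)
        """
    )
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    tmm = np.loadtxt(tmp / "tmm.txt")
    des = np.loadtxt(tmp / "des.txt")
    return counts, tmm, des


class TestEdgerAndDeseqCrossCheck:
    """Independent reference implementations (edgeR / DESeq2 via Rscript)
    must reproduce the TMM and median-of-ratios factors."""

    def test_tmm_matches_edger(self, r_factors):
        counts, tmm_r, _ = r_factors
        cm = CountMatrix(
            counts, [f"g{i}" for i in range(120)], [f"s{j}" for j in range(5)]
        )
        ours = tmm_factors(cm).factors
        np.testing.assert_allclose(
            ours / geomean(ours), tmm_r / geomean(tmm_r), rtol=1e-8
        )

    def test_median_ratio_matches_deseq(self, r_factors):
        counts, _, des_r = r_factors
        cm = CountMatrix(
            counts, [f"g{i}" for i in range(120)], [f"s{j}" for j in range(5)]
        )
        ours = median_ratio_factors(cm).factors
        # DESeq2 takes the median of *log* ratios; with an even gene count the
        # interpolated median differs from the ratio-space median by O(1e-4)
        np.testing.assert_allclose(
            ours / geomean(ours), des_r / geomean(des_r), rtol=1e-3
        )


class TestInvariantsAndErrors:
    @pytest.mark.parametrize("method", METHODS)
    def test_scaling_one_sample_scales_its_divisor(self, method, rng):
        cm = random_count_matrix(rng, n_genes=60, n_samples=4, low=1, high=200)
        scaled_counts = cm.counts.copy()
        c = 3
        scaled_counts[:, 1] *= c
        cm2 = CountMatrix(scaled_counts, cm.gene_ids, cm.sample_ids, cm.group_labels)
        if method == "RD":
            # the raw-data benchmark never rescales, whatever the depths
            np.testing.assert_array_equal(compute_factors(cm2, "RD").divisors, 1.0)
            return
        kwargs = {"reference": "s0"} if method == "TMM" else {}
        d1 = compute_factors(cm, method, **kwargs).divisors
        d2 = compute_factors(cm2, method, **kwargs).divisors
        # divisor of the scaled sample rises by c, up to the geometric-mean
        # rescale; exact for UQ/DES/EBS, approximate for TMM (the weights see
        # the library size) and PS (the GOF gene selection shifts)
        rtol = 0.05 if method in ("TMM", "PS") else 1e-9
        ratio = d2 / d1
        np.testing.assert_allclose(ratio[1] / ratio[0], c, rtol=rtol)

    @pytest.mark.parametrize("method", METHODS)
    def test_divisors_have_unit_geometric_mean(self, method, small_cm):
        sf = compute_factors(small_cm, method)
        assert abs(geomean(sf.divisors) - 1) < 1e-9

    def test_parameter_recovery_no_de(self):
        from normrank.synthetic_data import SyntheticSpec, generate_counts

        spec = SyntheticSpec(
            n_genes=5000,
            n_group1=5,
            n_group2=5,
            seed=424242,
            de_fraction=0.0,
            size_factor_sigma=0.4,
        )
        cm, truth = generate_counts(spec)
        for method in ("TMM", "UQ", "DES", "EBS", "PS"):
            div = compute_factors(cm, method).divisors
            r = np.corrcoef(div, truth.true_size_factors)[0, 1]
            assert r > 0.99, method
            rel = np.abs(div - truth.true_size_factors) / truth.true_size_factors
            assert rel.max() < 0.05, (method, rel.max())

    def test_unknown_method_and_misalignment(self, small_cm):
        with pytest.raises(NormalizationError, match="unknown method"):
            compute_factors(small_cm, "XX")
        sf = raw_factors(small_cm)
        other = CountMatrix(
            small_cm.counts, small_cm.gene_ids, [f"x{j}" for j in range(4)]
        )
        with pytest.raises(NormalizationError, match="aligned"):
            normalize_counts(other, sf)

    def test_uq_zero_quartile_names_sample(self):
        counts = np.array([[0, 5], [0, 5], [0, 5], [0, 5], [9, 5]])
        cm = CountMatrix(counts, list("abcde"), ["bad", "good"])
        with pytest.raises(NormalizationError, match="bad"):
            uq_factors(cm)

    def test_poissonseq_literal_window_usually_empty(self, small_cm):
        with pytest.raises(NormalizationError, match="widen"):
            poissonseq_factors(small_cm, literal_window=True)

    def test_normalize_divisor_arithmetic(self):
        cm = CountMatrix(np.array([[1, 4], [2, 8]]), ["g1", "g2"], ["a", "b"])
        sf = raw_factors(cm)
        sf.divisors = np.array([0.5, 2.0])
        np.testing.assert_allclose(
            normalize_counts(cm, sf), [[2.0, 2.0], [4.0, 4.0]]
        )
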