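import numpy as np
import pandas as pd
import pytest

from gnibench.normalization import (
    NormalizationFactors,
    apply_factors,
    apply_normalization,
    quantile_normalize,
    rle_factors,
    tmm_factors,
    vst_apply,
    vst_fit,
)
from gnibench.normalization import vst_transform_values


def _nb_counts(rng, n_genes, n_samples, mean_lo=10, mean_hi=1e4, disp=0.05):
    mu = np.exp(rng.uniform(np.log(mean_lo), np.log(mean_hi), size=n_genes))
    n_param = 1.0 / disp
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu[:, None]),
                                   size=(n_genes, n_samples))
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)], dtype=float), mu


def _tmm_oracle(counts: np.ndarray, trim_m=0.30, trim_a=0.05):
    """Direct-translation TMM: plain loops, no shared code with the implementation."""
    lib = counts.sum(axis=0)
    q75frac = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        q75frac.append(np.quantile(col[col > 0], 0.75) / lib[j])
    q75frac = np.array(q75frac)
    ref = int(np.argmin(np.abs(q75frac - q75frac.mean())))
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        o, r = counts[:, j], counts[:, ref]
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        M = np.log2((o / lib[j]) / (r / lib[ref]))
        A = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(M)
        loM, hiM = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        loA, hiA = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        w = 1.0 / v[sel]
        factors[j] = 2 ** (np.sum(w * M[sel]) / np.sum(w))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)), dtype=float)
        f = tmm_factors(m).factors
        assert np.allclose(f, 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=200).astype(float) + 1
        m = pd.DataFrame({"a": y, "b": 2 * y})
        assert np.allclose(tmm_factors(m).factors, 1.0)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(5)
        m, _ = _nb_counts(rng, 300, 6)
        f = tmm_factors(m).factors.to_numpy()
        expected = _tmm_oracle(m.to_numpy())
        assert np.allclose(f, expected, rtol=1e-10)

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(6)
        m, _ = _nb_counts(rng, 200, 5)
        f1 = tmm_factors(m).factors.to_numpy()
        f2 = tmm_factors(m * 3).factors.to_numpy()
        assert np.allclose(f1, f2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [1.0, 2.0]}))


class TestRle:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame(np.tile([[10], [20], [30]], (1, 3)), dtype=float)
        assert np.allclose(rle_factors(m).factors, 1.0)

    def test_depth_doubling_gives_sqrt2_factors(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(100, size=100).astype(float) + 1
        m = pd.DataFrame({"a": y, "b": 2 * y})
        f = rle_factors(m).factors
        assert f["a"] == pytest.approx(1 / np.sqrt(2))
        assert f["b"] == pytest.approx(np.sqrt(2))

    def test_matches_median_of_ratios_brute_force(self):
        rng = np.random.default_rng(2)
        m, _ = _nb_counts(rng, 150, 5)
        f = rle_factors(m).factors.to_numpy()
        counts = m.to_numpy()
        allpos = (counts > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(counts[allpos]), axis=1))
        raw = np.array([np.median(counts[allpos, j] / geo) for j in range(5)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f, expected)

    def test_all_zero_gene_overlap_errors(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            rle_factors(m)

    def test_product_one_standardization(self):
        rng = np.random.default_rng(3)
        m, _ = _nb_counts(rng, 100, 7)
        for nf in (rle_factors(m), tmm_factors(m)):
            assert np.prod(nf.factors.to_numpy()) == pytest.approx(1.0, rel=1e-10)


class TestApplyFactors:
    def test_unit_factors_identity(self, toy_counts):
        nf = NormalizationFactors(
            factors=pd.Series(1.0, index=toy_counts.columns),
            library_sizes=toy_counts.sum(axis=0),
        )
        pd.testing.assert_frame_equal(apply_factors(toy_counts, nf), toy_counts)

    def test_factor_two_halves_column(self, toy_counts):
        f = pd.Series([2.0, 1.0, 1.0], index=toy_counts.columns)
        nf = NormalizationFactors(factors=f, library_sizes=toy_counts.sum(axis=0))
        out = apply_factors(toy_counts, nf)
        assert np.allclose(out["s1"], toy_counts["s1"] / 2)
        assert np.allclose(out["s2"], toy_counts["s2"])

    def test_column_sums_scale_inversely(self, toy_counts):
        f = pd.Series([0.5, 1.0, 2.0], index=toy_counts.columns)
        nf = NormalizationFactors(factors=f, library_sizes=toy_counts.sum(axis=0))
        out = apply_factors(toy_counts, nf)
        assert np.allclose(out.sum(axis=0), toy_counts.sum(axis=0) / f)


class TestVst:
    def test_monotone_in_x(self):
        rng = np.random.default_rng(4)
        m, _ = _nb_counts(rng, 300, 20)
        fit = vst_fit(m)
        x = np.linspace(0.5, 1e5, 500)
        y = vst_transform_values(x, fit)
        assert (np.diff(y) > 0).all()

    def test_large_x_slope_approaches_log2(self):
        rng = np.random.default_rng(4)
        m, _ = _nb_counts(rng, 300, 20)
        fit = vst_fit(m)
        for x0 in (1e4, 1e5):
            num = vst_transform_values(np.array([x0 * 1.01]), fit)[0] - \
                  vst_transform_values(np.array([x0]), fit)[0]
            den = np.log2(x0 * 1.01) - np.log2(x0)
            assert num / den == pytest.approx(1.0, abs=0.01)

    def test_variance_flattening_on_nb_simulation(self):
        """VST evens out per-gene variances across mean bins; log2 does not."""
        rng = np.random.default_rng(0)
        m, mu = _nb_counts(rng, 300, 60, disp=0.05)
        fit = vst_fit(m)
        assert fit.a0 == pytest.approx(0.05, rel=0.25)
        transformed = vst_apply(m, fit)
        logged = np.log2(m + 1)

        def bin_variance_ratio(x):
            order = np.argsort(mu)
            gene_vars = x.var(axis=1).to_numpy()[order]
            bins = [gene_vars[i:i + 50].mean() for i in range(0, 250, 25)]
            return max(bins) / min(bins)

        assert bin_variance_ratio(transformed) < 3.0
        assert bin_variance_ratio(transformed) < bin_variance_ratio(logged)

    def test_fallback_on_degenerate_dispersions(self):
        # Poisson-like data: moment dispersions are ~0, so the trend is unfittable
        rng = np.random.default_rng(9)
        m = pd.DataFrame(np.tile(rng.integers(5, 50, size=(12, 1)), (1, 5)),
                         dtype=float)
        fit = vst_fit(m)
        assert fit.fallback
        out = vst_apply(m, fit)
        assert np.allclose(out, np.log2(m / fit.size_factors + 1))


class TestQuantileNormalize:
    def test_forced_by_algorithm(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_columns_share_value_multiset(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.uniform(size=(50, 4)))
        out = quantile_normalize(m)
        ref = np.sort(out[0].to_numpy())
        for j in range(1, 4):
            assert np.allclose(np.sort(out[j].to_numpy()), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.uniform(size=(30, 3)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)


class TestApplyNormalization:
    def test_nonorm_identity(self, toy_counts):
        m = toy_counts + 1
        pd.testing.assert_frame_equal(apply_normalization(m, m, "NoNorm"), m)

    def test_tmm_identity_on_identical_columns(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 3)), dtype=float)
        m = counts * 7
        pd.testing.assert_frame_equal(apply_normalization(m, counts, "TMM"), m)

    def test_qn_column_distributions_identical(self, toy_counts):
        m = toy_counts + 1
        out = apply_normalization(m, m, "QN")
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_unknown_method_errors(self, toy_counts):
        with pytest.raises(ValueError):
            apply_normalization(toy_counts, toy_counts, "UQ")
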