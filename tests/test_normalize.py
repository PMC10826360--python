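"""Normalization strategies: thresholds, proportions, subsampling,
rarefaction averaging, variance stabilization, upper-quartile log-CPM."""

import numpy as np
import pytest

import rarebench as rb
from rarebench.normalize import (fit_dispersion_curve,
                                 median_of_ratios_size_factors,
                                 normalize_raw, subsample_counts,
                                 vst_transform)


class TestPickThreshold:
    depths = np.arange(1, 81) * 100  # 80 distinct depths

    def test_quantile_zero_keeps_everyone(self):
        params = rb.pick_threshold(self.depths, 0)
        assert params.n_l_m == 100
        assert params.removed_mask.sum() == 0

    def test_quantile_15_removes_12_of_80(self):
        params = rb.pick_threshold(self.depths, 15)
        assert params.removed_mask.sum() == 12
        assert params.n_l_m == self.depths[12]  # smallest retained depth

    @pytest.mark.parametrize("q", [0, 5, 10, 15, 20, 25, 40])
    def test_equal_depths_remove_nothing(self, q):
        params = rb.pick_threshold(np.full(80, 500), q)
        assert params.removed_mask.sum() == 0 and params.n_l_m == 500

    def test_unlisted_quantile_rejected(self):
        with pytest.raises(ValueError):
            rb.pick_threshold(self.depths, 17)


class TestRelabund:
    def test_row_proportions(self, toy_table):
        norm = rb.normalize_relabund(toy_table)
        np.testing.assert_allclose(norm.values.sum(axis=1), 1.0)
        np.testing.assert_allclose(norm.values[0],
                                   np.array([5, 0, 3, 2]) / 10)

    def test_invariant_to_depth_rescaling(self, toy_table):
        import dataclasses
        scaled = dataclasses.replace(toy_table, counts=toy_table.counts * 7)
        np.testing.assert_allclose(rb.normalize_relabund(scaled).values,
                                   rb.normalize_relabund(toy_table).values)

    def test_zero_row_rejected(self, toy_table):
        import dataclasses
        counts = toy_table.counts.copy()
        counts[1] = 0
        bad = dataclasses.replace(toy_table, counts=counts)
        with pytest.raises(ValueError):
            rb.normalize_relabund(bad)


class TestSubsample:
    def test_exhaustive_draw_is_identity(self):
        rng = np.random.default_rng(0)
        row = np.array([4, 0, 6])
        np.testing.assert_array_equal(subsample_counts(row, 10, rng), row)

    def test_single_support_draw(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(subsample_counts(np.array([5, 0]), 3, rng),
                                      [3, 0])

    def test_rows_sum_to_minimum_library_size(self, null_table):
        params = rb.pick_threshold(null_table.depths, 15, seed=3)
        norm = rb.subsample_once(null_table, params, 15)
        np.testing.assert_array_equal(norm.values.sum(axis=1), params.n_l_m)
        assert len(norm.sample_ids) == 68 and len(norm.removed_samples) == 12

    def test_hypergeometric_mean(self):
        """E[subsampled count] = n * c_g / depth over repeated draws."""
        row = np.array([50, 30, 15, 5])
        n = 40
        rng = np.random.default_rng(1)
        draws = np.array([subsample_counts(row, n, rng) for _ in range(10000)])
        expect = n * row / row.sum()
        total = row.sum()
        var = (n * (row / total) * (1 - row / total)
               * (total - n) / (total - 1))
        se = np.sqrt(var / 10000)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()

    def test_too_shallow_sample_rejected(self, toy_table):
        params = rb.RarefactionParams(n_l_m=100)
        with pytest.raises(ValueError):
            rb.subsample_once(toy_table, params)


class TestRarefyMetric:
    def test_one_iteration_equals_single_subsample(self, null_table):
        params = rb.pick_threshold(null_table.depths, 0, n_iterations=1, seed=5)
        norm = rb.subsample_once(null_table, params, 0)
        avg, ids, removed = rb.rarefy_metric(
            null_table, params, lambda draw: draw.astype(float))
        np.testing.assert_array_equal(avg, norm.values)
        assert ids == norm.sample_ids

    def test_expected_richness_matches_closed_form(self):
        row = np.array([20, 10, 5, 2, 1, 1])
        t = rb.CountTable(counts=np.vstack([row, row, row, row]),
                          groups=np.array(["A", "A", "B", "B"]),
                          otu_ids=list("abcdef"),
                          sample_ids=["s1", "s2", "s3", "s4"])
        params = rb.RarefactionParams(n_l_m=10, n_iterations=2000, seed=0)
        avg, _, _ = rb.rarefy_metric(
            t, params, lambda draw: [(r > 0).sum() for r in draw])
        closed = rb.expected_rarefied_richness(row, 10)
        # Monte-Carlo SE of a mean of 4x2000 bounded-by-6 richness values
        assert abs(avg.mean() - closed) < 0.05

    def test_rarefied_metric_less_variable_than_single_subsample(self, null_table):
        """Averaging over draws shrinks the subsampling noise."""
        params0 = rb.pick_threshold(null_table.depths, 0, seed=0)

        def mean_bray(seed, iters):
            p = rb.RarefactionParams(n_l_m=params0.n_l_m, n_iterations=iters,
                                     seed=seed)
            avg, _, _ = rb.rarefy_metric(
                null_table, p,
                lambda draw: rb.distance_matrix(
                    rb.NormalizedTable(values=draw.astype(float),
                                       sample_ids=null_table.sample_ids,
                                       otu_ids=null_table.otu_ids,
                                       groups=null_table.groups,
                                       method="subsample"), "bray").values)
            return avg[0, 1]

        single = [mean_bray(s, 1) for s in range(40)]
        rarefied = [mean_bray(s, 20) for s in range(40)]
        assert np.var(rarefied) < np.var(single)

    def test_averaged_matrix_within_iteration_envelope(self, null_table):
        params = rb.pick_threshold(null_table.depths, 0, n_iterations=10, seed=2)
        mats = []
        sub_params = rb.RarefactionParams(n_l_m=params.n_l_m, n_iterations=10,
                                          seed=2)

        def collect(draw):
            m = rb.distance_matrix(
                rb.NormalizedTable(values=draw.astype(float),
                                   sample_ids=null_table.sample_ids,
                                   otu_ids=null_table.otu_ids,
                                   groups=null_table.groups,
                                   method="subsample"), "bray").values
            mats.append(m)
            return m

        avg, _, _ = rb.rarefy_metric(null_table, sub_params, collect)
        stack = np.array(mats)
        assert (avg >= stack.min(axis=0) - 1e-12).all()
        assert (avg <= stack.max(axis=0) + 1e-12).all()


class TestVst:
    def test_identical_samples_unit_size_factors(self):
        counts = np.tile(np.array([10, 5, 0, 3]), (2, 1))
        np.testing.assert_allclose(median_of_ratios_size_factors(counts),
                                   [1.0, 1.0])

    def test_monotone_within_sample(self, null_table):
        norm = rb.normalize_vst(null_table)
        order_in = np.argsort(null_table.counts[0], kind="stable")
        transformed = norm.values[0][order_in]
        assert (np.diff(transformed) >= -1e-12).all()

    def test_asymptotically_log2(self):
        a0, a1 = 0.5, 0.1
        q = np.array([1e6, 2e6])
        delta = vst_transform(q[1:], a0, a1) - vst_transform(q[:1], a0, a1)
        assert abs(delta[0] / (np.log2(q[1]) - np.log2(q[0])) - 1) < 1e-3

    def test_variance_flattened_on_nb_counts(self):
        """Per-OTU variance after VST is near-constant across mean bins."""
        rng = np.random.default_rng(8)
        alpha = 0.3
        mus = np.geomspace(5, 5000, 60)
        counts = rng.negative_binomial(n=1 / alpha,
                                       p=1 / (1 + alpha * np.tile(mus, (100, 1))))
        t = rb.CountTable(counts=counts,
                          groups=np.array(["A"] * 50 + ["B"] * 50),
                          otu_ids=[f"o{i}" for i in range(60)],
                          sample_ids=[f"s{i}" for i in range(100)])
        norm = rb.normalize_vst(t)
        variances = norm.values.var(axis=0, ddof=1)
        bins = np.array_split(variances, 4)  # OTUs are ordered by mean
        bin_vars = [np.mean(b) for b in bins]
        assert max(bin_vars) / min(bin_vars) < 3

    def test_nonpositive_asymptotic_dispersion_falls_back(self, caplog):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(20, 30))  # Poisson: no overdispersion
        sf = np.ones(20)
        with caplog.at_level("WARNING", logger="rarebench.normalize"):
            a0, a1 = fit_dispersion_curve(counts + 1.0, sf)
        assert a1 > 0

    def test_negative_fraction_diagnostics(self):
        norm = rb.NormalizedTable(values=np.array([[1.0, -2.0], [3.0, 4.0]]),
                                  sample_ids=["s1", "s2"], otu_ids=["a", "b"],
                                  groups=np.array(["A", "B"]), method="vst")
        frac, any_neg = rb.detect_negative_fraction(norm)
        assert frac == 0.25 and any_neg

    def test_negative_fraction_requires_vst(self, toy_table):
        with pytest.raises(ValueError):
            rb.detect_negative_fraction(normalize_raw(toy_table))


class TestUpperQuartile:
    def test_identical_samples_identical_rows(self):
        counts = np.tile(np.array([40, 10, 0, 50]), (3, 1))
        t = rb.CountTable(counts=counts, groups=np.array(["A", "A", "B"]),
                          otu_ids=list("abcd"), sample_ids=["s1", "s2", "s3"])
        norm = rb.normalize_uq(t)
        # identical samples: unit factors, so every normalized row matches
        np.testing.assert_allclose(norm.values[0], norm.values[1])
        np.testing.assert_allclose(norm.values[0], norm.values[2])

    def test_doubling_a_sample_leaves_its_logcpm_unchanged(self, toy_table):
        import dataclasses
        norm = rb.normalize_uq(toy_table)
        counts = toy_table.counts.copy()
        counts[2] *= 2
        doubled = rb.normalize_uq(dataclasses.replace(toy_table, counts=counts))
        np.testing.assert_allclose(doubled.values[2], norm.values[2], rtol=1e-9)

    def test_factors_geometric_mean_one(self, null_table):
        counts = null_table.counts
        depths = null_table.depths.astype(float)
        factors = np.array([np.quantile(r[r > 0], 0.75) for r in counts]) / depths
        factors /= np.exp(np.mean(np.log(factors)))
        assert abs(np.exp(np.mean(np.log(factors))) - 1) < 1e-9

    def test_all_zero_sample_rejected(self, toy_table):
        import dataclasses
        counts = toy_table.counts.copy()
        counts[0] = 0
        with pytest.raises(ValueError):
            rb.normalize_uq(dataclasses.replace(toy_table, counts=counts))
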