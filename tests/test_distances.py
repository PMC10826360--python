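"""Distance calculations and the normalization/distance pairing rules."""

import io as stdio

import numpy as np
import pytest
from skbio import TreeNode

import rarebench as rb
from rarebench.distances import (ADMISSIBLE_PAIRS, _bray_matrix,
                                 poisson_distance, top_msd, unifrac)
from rarebench.normalize import normalize_raw, normalize_relabund, \
    normalize_uq, normalize_vst


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert rb.bray_curtis([1, 2, 3], [1, 2, 3]) == 0
        assert rb.bray_curtis([1, 0], [0, 4]) == 1

    def test_hand_value(self):
        assert rb.bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            rb.bray_curtis([0, 0], [0, 0])

    def test_matrix_agrees_with_pairwise(self, null_table):
        v = null_table.counts[:6].astype(float)
        m = _bray_matrix(v)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(
                    0 if i == j else rb.bray_curtis(v[i], v[j]))


class TestEuclidean:
    def test_examples(self):
        assert rb.euclidean([1, 1], [1, 1]) == 0
        assert rb.euclidean([0, 0], [3, 4]) == 5

    def test_sign_safe(self):
        assert rb.euclidean([-1, 0], [1, 0]) == 2


class TestPoissonDistance:
    def test_identical_samples_zero(self):
        counts = np.array([[5, 3, 2], [5, 3, 2]])
        dm = poisson_distance(counts, ["s1", "s2"], transform=False)
        assert dm.values[0, 1] == pytest.approx(0, abs=1e-12)

    def test_two_sample_toy_matches_deviance_formula(self):
        """Hand-coded Poisson log-likelihood-ratio on a 2x2 toy table."""
        x = np.array([[4.0, 1.0], [2.0, 3.0]])
        ni, nj = x[0].sum(), x[1].sum()
        expected = 0.0
        for g in range(2):
            pooled = x[0, g] + x[1, g]
            mu_i, mu_j = pooled * ni / (ni + nj), pooled * nj / (ni + nj)
            expected += x[0, g] * np.log(x[0, g] / mu_i)
            expected += x[1, g] * np.log(x[1, g] / mu_j)
        dm = poisson_distance(x.astype(int), ["s1", "s2"], transform=False)
        assert dm.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_symmetric_nonnegative(self, null_table):
        dm = poisson_distance(null_table.counts[:8],
                              null_table.sample_ids[:8])
        assert (dm.values >= -1e-12).all()
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance(np.array([[0.5, 1.0]]), ["s1"])


def brute_force_unifrac(tree: TreeNode, x: np.ndarray, y: np.ndarray,
                        otu_ids: list[str], weighted: bool) -> float:
    """Direct UniFrac by enumerating every branch of the tree."""
    idx = {o: i for i, o in enumerate(otu_ids)}
    xt, yt = x.sum(), y.sum()
    num = denom = 0.0
    for node in tree.postorder():
        if node.is_root() or node.length is None:
            continue
        tips = [t.name for t in (node.tips() if not node.is_tip() else [node])]
        xa = sum(x[idx[t]] for t in tips)
        ya = sum(y[idx[t]] for t in tips)
        if weighted:
            num += node.length * abs(xa / xt - ya / yt)
            denom += node.length * (xa / xt + ya / yt)
        else:
            if (xa > 0) != (ya > 0):
                num += node.length
            if xa > 0 or ya > 0:
                denom += node.length
    return num / denom


class TestUniFrac:
    def random_case(self, seed):
        from rarebench.parents import random_bifurcating_tree
        rng = np.random.default_rng(seed)
        otus = [f"t{i}" for i in range(8)]
        tree = random_bifurcating_tree(otus, rng)
        counts = rng.integers(0, 20, size=(2, 8))
        counts[0, rng.integers(0, 8)] += 1  # avoid all-zero rows
        counts[1, rng.integers(0, 8)] += 1
        return tree, counts, otus

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_branch_enumeration_oracle(self, seed, weighted):
        tree, counts, otus = self.random_case(seed)
        dm = unifrac(counts, ["s1", "s2"], otus, tree, weighted=weighted,
                     normalized_w=True)
        oracle = brute_force_unifrac(tree, counts[0].astype(float),
                                     counts[1].astype(float), otus, weighted)
        assert dm.values[0, 1] == pytest.approx(oracle, abs=1e-9)

    def test_identical_rows_zero(self):
        tree, counts, otus = self.random_case(7)
        counts[1] = counts[0]
        for weighted in (False, True):
            dm = unifrac(counts, ["s1", "s2"], otus, tree, weighted=weighted)
            assert dm.values[0, 1] == pytest.approx(0, abs=1e-9)

    def test_two_leaf_disjoint(self):
        tree = TreeNode.read(stdio.StringIO("(x:1,y:1);"))
        counts = np.array([[5, 0], [0, 3]])
        u = unifrac(counts, ["s1", "s2"], ["x", "y"], tree, weighted=False)
        w = unifrac(counts, ["s1", "s2"], ["x", "y"], tree, weighted=True)
        assert u.values[0, 1] == pytest.approx(1.0)
        assert w.values[0, 1] == pytest.approx(1.0)

    def test_unweighted_scale_invariant(self):
        tree, counts, otus = self.random_case(9)
        dm1 = unifrac(counts, ["s1", "s2"], otus, tree, weighted=False)
        dm2 = unifrac(counts * 13, ["s1", "s2"], otus, tree, weighted=False)
        np.testing.assert_allclose(dm1.values, dm2.values)

    def test_missing_otu_named(self):
        tree = TreeNode.read(stdio.StringIO("(x:1,y:1);"))
        with pytest.raises(ValueError, match="ghost"):
            unifrac(np.array([[1, 1]]), ["s1"], ["ghost"], tree, weighted=False)


class TestTopMsd:
    def test_identical_rows_zero(self):
        dm = top_msd(np.array([[1.0, 2.0], [1.0, 2.0]]), ["s1", "s2"], n_top=2)
        assert dm.values[0, 1] == 0

    def test_all_otus_collapses_to_rms(self):
        x = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0]])
        dm = top_msd(x, ["s1", "s2"], n_top=3)
        assert dm.values[0, 1] == pytest.approx(np.sqrt((1 + 4 + 4) / 3))

    def test_top_two_of_three(self):
        x = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        dm = top_msd(x, ["s1", "s2"], n_top=2)
        assert dm.values[0, 1] == pytest.approx(np.sqrt((4 + 9) / 2))

    def test_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            top_msd(np.zeros((2, 3)), ["s1", "s2"], n_top=10)


class TestPairingRules:
    def test_vst_bray_is_na(self, null_table):
        norm = normalize_vst(null_table)
        assert rb.distance_matrix(norm, "bray") is None

    def test_vst_bray_allowed_in_pathology_mode(self, null_table):
        norm = normalize_vst(null_table)
        dm = rb.distance_matrix(norm, "bray", pathology=True)
        assert dm is not None

    def test_uq_only_feeds_top_msd(self, null_table):
        norm = normalize_uq(null_table)
        assert rb.distance_matrix(norm, "bray") is None
        assert rb.distance_matrix(norm, "top_msd") is not None

    def test_admissible_counts_match_pairing_table(self):
        expected = {"raw": 4, "relabund": 3, "subsample": 6, "rarefy": 6,
                    "vst": 1, "uq_logfc": 1}
        assert {k: len(v) for k, v in ADMISSIBLE_PAIRS.items()} == expected

    @pytest.mark.parametrize("method", ["bray", "euclidean", "poisson"])
    def test_matrices_symmetric_zero_diagonal(self, null_table, method):
        norm = (normalize_raw(null_table) if method != "bray"
                else normalize_relabund(null_table))
        dm = rb.distance_matrix(norm, method)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(dm.values), 0, atol=1e-10)
        if method == "bray":
            assert (dm.values <= 1 + 1e-12).all() and (dm.values >= 0).all()
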