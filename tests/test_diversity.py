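"""Alpha/beta diversity, NMDS, PERMANOVA and FDR against closed forms and brute force."""
import itertools

import numpy as np
import pandas as pd
import pytest

from bioind.diversity import (
    DistanceMatrix,
    bray_curtis,
    fdr_adjust,
    nmds,
    observed_asvs,
    pairwise_permanova,
    permanova,
    shannon,
)
from bioind.tables import AbundanceTable, TableError


class TestAlpha:
    def test_closed_forms(self):
        assert observed_asvs([1, 0, 0]) == 1
        assert shannon([1, 0, 0]) == 0.0
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)
        # direct summation: -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-12)

    def test_uniform_maximizes_shannon(self, rng):
        k = 6
        uniform = shannon(np.full(k, 1.0 / k))
        for _ in range(20):
            p = rng.dirichlet(np.ones(k))
            assert shannon(p) <= uniform + 1e-12

    def test_observed_permutation_invariant(self, rng):
        row = rng.integers(0, 5, size=30)
        row[0] = 1
        assert observed_asvs(row) == observed_asvs(row[::-1])

    def test_all_zero_errors(self):
        with pytest.raises(TableError):
            shannon([0, 0])
        with pytest.raises(TableError):
            observed_asvs([0, 0])


def _table(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return AbundanceTable(
        pd.DataFrame(rows, index=ids, columns=[f"a{j}" for j in range(len(rows[0]))]),
        "counts",
    )


class TestBrayCurtis:
    def test_hand_value(self):
        dm = bray_curtis(_table([[6, 2], [2, 2]]))
        assert dm.values[0, 1] == pytest.approx(4 / 12, abs=1e-12)

    def test_identical_and_disjoint(self):
        dm = bray_curtis(_table([[3, 1, 0], [3, 1, 0], [0, 0, 9]]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0

    def test_symmetry_bounds_zero_iff_equal(self, rng):
        rows = rng.integers(0, 20, size=(8, 5)) + 1
        dm = bray_curtis(_table(rows))
        assert np.allclose(dm.values, dm.values.T)
        assert dm.values.min() >= 0 and dm.values.max() <= 1
        for i, j in itertools.combinations(range(8), 2):
            if not np.array_equal(rows[i], rows[j]):
                assert dm.values[i, j] > 0


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, .5, .5], [.5, 0, .5], [.5, .5, 0]]))
        _, stress = nmds(dm, k=2, n_restarts=4, seed=0)
        assert stress < 1e-3

    def test_euclidean_configuration_recovered(self, rng):
        pts = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        d /= d.max()
        dm = DistanceMatrix([f"s{i}" for i in range(9)], d)
        coords, stress = nmds(dm, k=2, n_restarts=8, seed=1)
        assert stress < 0.01
        assert coords.shape == (9, 2)

    def test_k_too_large(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(TableError):
            nmds(dm, k=2)


def _two_cluster_dm(gap=0.9):
    ids = ["a1", "a2", "b1", "b2"]
    d = np.full((4, 4), gap)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


def _pseudo_f(d2, groups):
    """Anderson (2001) pseudo-F from squared dissimilarities, brute force."""
    n = len(groups)
    labels = np.asarray(groups)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    a = len(np.unique(labels))
    return (ssa / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_maximal_separation_approaches_min_p(self):
        # 5+5 clusters with zero within- and large between-distance: only a
        # permutation reproducing the observed partition ties the observed F
        # (probability 2*5!*5!/10! ~ 0.8%), so p sits near its 1/(n+1) floor
        n = 10
        d = np.full((n, n), 0.9)
        d[:5, :5] = 0.0
        d[5:, 5:] = 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        res = permanova(dm, ["g1"] * 5 + ["g2"] * 5, n_permutations=999, seed=0)
        assert 1 / 1000 <= res.p_value <= 0.03

    def test_sampled_p_matches_exhaustive_enumeration(self):
        # brute-force oracle: enumerate all 4!/(2!2!) = 6 distinct relabelings
        dm = _two_cluster_dm(gap=0.7)
        labels = ["g1", "g1", "g2", "g2"]
        d2 = dm.values**2
        f_obs = _pseudo_f(d2, labels)
        perms = set(itertools.permutations([0, 0, 1, 1]))
        f_all = [_pseudo_f(d2, list(p)) for p in perms]
        p_exact = sum(f >= f_obs - 1e-12 for f in f_all) / len(f_all)
        res = permanova(dm, labels, n_permutations=1000, seed=2)
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-9)
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(res.p_value - p_exact) <= 3 * mc_sd + 2 / 1001

    def test_relabeling_within_groups_leaves_f_unchanged(self):
        dm = _two_cluster_dm()
        f1 = permanova(dm, ["x", "x", "y", "y"], n_permutations=9, seed=0).pseudo_f
        swapped = DistanceMatrix(
            ["a2", "a1", "b1", "b2"],
            dm.values[np.ix_([1, 0, 2, 3], [1, 0, 2, 3])],
        )
        f2 = permanova(swapped, ["x", "x", "y", "y"], n_permutations=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_singleton_group_rejected(self):
        dm = _two_cluster_dm()
        with pytest.raises(TableError):
            permanova(dm, ["g1", "g2", "g2", "g2"])

    def test_pairwise_contrasts_jointly_adjusted(self):
        ids = [f"s{i}" for i in range(6)]
        d = np.full((6, 6), 0.8)
        for i in range(0, 6, 2):
            d[i, i + 1] = d[i + 1, i] = 0.05
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(ids, d)
        out = pairwise_permanova(dm, ["u", "u", "v", "v", "w", "w"],
                                 n_permutations=99, seed=0)
        assert len(out) == 3
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestFDR:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_and_ties(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([0.4, 0.4, 0.4]), [0.4] * 3)

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(size=40)
        assert (fdr_adjust(p) >= p - 1e-12).all()

    def test_out_of_range(self):
        with pytest.raises(TableError):
            fdr_adjust([1.2])
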