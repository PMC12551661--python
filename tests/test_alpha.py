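"""Alpha diversity metrics against independent oracles and identities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import streamfd as sfd
from streamfd.alpha import alpha_metrics_at, feve, fdis, fric, rao_simpson_redundancy

from conftest import make_trait_table


def feve_oracle(dist: np.ndarray, p: np.ndarray) -> float:
    """FEve via exhaustive enumeration of all labeled spanning trees.

    Labeled trees on S vertices are enumerated through Prufer sequences
    (S^(S-2) trees); the minimum-total-distance tree is selected and the
    evenness formula applied to it.  Independent of the Prim-based
    implementation.
    """
    s = len(p)
    best_edges, best_w = None, np.inf
    for seq in itertools.product(range(s), repeat=s - 2):
        edges = _prufer_decode(list(seq), s)
        w = sum(dist[i, j] for i, j in edges)
        if w < best_w - 1e-15:
            best_w, best_edges = w, edges
    ew = np.array([dist[i, j] / (p[i] + p[j]) for i, j in best_edges])
    pew = ew / ew.sum()
    thr = 1.0 / (s - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)


def _prufer_decode(seq, s):
    degree = np.ones(s, dtype=int)
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    leaves = sorted(v for v in range(s) if degree[v] == 1)
    for v in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            import bisect

            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


class TestCwm:
    def test_single_taxon_equals_profile(self, toy_traits):
        com = pd.Series({"t1": 5.0, "t2": 0.0, "t3": 0.0})
        out = sfd.cwm(com, toy_traits)
        pd.testing.assert_series_equal(
            out, toy_traits.affinities.loc["t1"], check_names=False
        )

    def test_equal_abundance_midpoint(self):
        t = sfd.normalize_fuzzy(
            make_trait_table({"a": [1, 0], "b": [0, 1]}, [("g", ["x", "y"])])
        )
        out = sfd.cwm(pd.Series({"a": 2.0, "b": 2.0}), t)
        assert out.tolist() == [0.5, 0.5]

    def test_weighted_mean_hand_computed(self):
        t = sfd.normalize_fuzzy(
            make_trait_table(
                {"a": [1, 0], "b": [0.5, 0.5], "c": [0, 1]}, [("g", ["x", "y"])]
            )
        )
        out = sfd.cwm(pd.Series({"a": 1.0, "b": 2.0, "c": 7.0}), t)
        # p = (.1, .2, .7): CWM_x = .1 + .2*.5 = .2, CWM_y = .2*.5 + .7 = .8
        np.testing.assert_allclose(out.to_numpy(), [0.2, 0.8], atol=1e-15)

    def test_missing_trait_profile_rejected(self, toy_traits):
        with pytest.raises(ValueError, match="without trait"):
            sfd.cwm(pd.Series({"t1": 1.0, "zz": 1.0}), toy_traits)


class TestFric:
    def test_unit_tetrahedron_volume(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert fric(pts) == pytest.approx(1 / 6, abs=1e-15)

    def test_pool_standardization_self_is_one(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=(30, 3))
        vol = fric(pool)
        assert fric(pool, standardize_volume=vol) == pytest.approx(1.0)

    def test_interior_point_leaves_volume_unchanged(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        with_interior = np.vstack([pts, pts.mean(axis=0)])
        assert fric(with_interior) == pytest.approx(fric(pts), abs=1e-15)

    def test_degenerate_sets_flagged_nan(self):
        coplanar = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.5, 0.5, 0]], dtype=float
        )
        assert np.isnan(fric(coplanar))
        assert np.isnan(fric(np.eye(3)))  # S <= m

    def test_monte_carlo_volume_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            s = rng.integers(5, 8)
            pts = rng.uniform(size=(s, 3))
            v = fric(pts)
            if np.isnan(v):
                continue
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            samples = rng.uniform(lo, hi, size=(100_000, 3))
            from scipy.spatial import ConvexHull

            eq = ConvexHull(pts).equations
            frac = ((samples @ eq[:, :3].T + eq[:, 3] <= 1e-12).all(axis=1)).mean()
            est = frac * np.prod(hi - lo)
            se = np.prod(hi - lo) * np.sqrt(frac * (1 - frac) / 100_000)
            assert abs(v - est) < max(3 * se, 0.02 * v)


class TestFeve:
    def test_regular_collinear_equal_abundance_is_one(self):
        pts = np.arange(5.0)[:, None]
        d = squareform(pdist(pts))
        p = np.full(5, 0.2)
        assert feve(d, p) == pytest.approx(1.0, abs=1e-12)

    def test_clumped_abundances_reduce_evenness(self):
        pts = np.arange(5.0)[:, None]
        d = squareform(pdist(pts))
        p = np.array([0.9, 0.025, 0.025, 0.025, 0.025])
        assert feve(d, p) < 1.0

    def test_small_community_undefined(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.isnan(feve(d, np.array([0.5, 0.5])))

    def test_matches_exhaustive_spanning_tree_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            s = int(rng.integers(4, 8))
            pts = rng.normal(size=(s, 3))
            d = squareform(pdist(pts))
            p = rng.dirichlet(np.ones(s))
            assert feve(d, p) == pytest.approx(feve_oracle(d, p), abs=1e-12)


class TestFdis:
    def test_single_taxon_zero(self):
        assert fdis(np.array([[1.0, 2.0]]), np.array([1.0])) == 0.0

    def test_two_equal_taxa_half_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert fdis(pts, np.array([0.5, 0.5])) == pytest.approx(2.5)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 4))
        p = rng.dirichlet(np.ones(6))
        assert fdis(pts + 17.3, p) == pytest.approx(fdis(pts, p), abs=1e-9)


class TestRaoSimpsonRedundancy:
    def test_equal_distance_identity(self):
        # with all pairwise d = delta: Q = delta * D, so FR = delta exactly
        rng = np.random.default_rng(6)
        delta = 0.37
        for s in (2, 5, 9):
            d = delta * (1 - np.eye(s))
            p = rng.dirichlet(np.ones(s))
            q, simpson, fr = rao_simpson_redundancy(d, p)
            assert q == pytest.approx(delta * simpson, abs=1e-12)
            assert fr == pytest.approx(delta, abs=1e-12)

    def test_identical_taxa_zero_entropy(self):
        d = np.zeros((4, 4))
        q, simpson, fr = rao_simpson_redundancy(d, np.full(4, 0.25))
        assert q == 0.0 and fr == 0.0

    def test_double_loop_oracle(self):
        d = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.7], [0.4, 0.7, 0.0]])
        p = np.array([0.2, 0.3, 0.5])
        q, simpson, fr = rao_simpson_redundancy(d, p)
        q_oracle = sum(
            d[i, j] * p[i] * p[j] for i in range(3) for j in range(3)
        )
        assert q == pytest.approx(q_oracle, abs=1e-15)
        assert q_oracle == pytest.approx(0.302)

    def test_monoculture_redundancy_undefined(self):
        q, simpson, fr = rao_simpson_redundancy(np.zeros((1, 1)), np.array([1.0]))
        assert simpson == 0.0 and np.isnan(fr)

    def test_entropy_bounded_by_max_distance(self, tiny_prepared):
        _, merged, space, _, _ = tiny_prepared
        d = space.distance.to_numpy()
        for idx, p in merged.site_indices(space.taxa).values():
            sub = d[np.ix_(idx, idx)]
            q, simpson, _ = rao_simpson_redundancy(sub, p)
            assert q <= sub.max() * simpson + 1e-12


class TestInvariances:
    def test_metrics_invariant_to_abundance_scaling(self, tiny_prepared):
        _, merged, space, _, _ = tiny_prepared
        site = merged.abundance.index[0]
        com = merged.abundance.loc[site]
        scaled = merged.abundance.copy()
        scaled.loc[site] = com * 13.0
        m2 = sfd.CommunityMatrix(
            abundance=scaled, sites=merged.sites, ept_flags=merged.ept_flags
        )
        a1, _ = sfd.compute_alpha(merged, space, _trait_of(tiny_prepared))
        a2, _ = sfd.compute_alpha(m2, space, _trait_of(tiny_prepared))
        pd.testing.assert_series_equal(a1.loc[site], a2.loc[site])

    def test_fric_invariant_to_point_order(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        assert fric(pts) == pytest.approx(fric(pts[::-1]), abs=1e-12)


def _trait_of(prepared):
    return prepared[0]
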