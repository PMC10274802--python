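"""Skeleton preprocessing and NBLAST-style scoring."""

import numpy as np
import pandas as pd
import pytest

from ahntools import morphology as mo
from ahntools.model import ConfigError, Skeleton, Units, ValidationError
from ahntools.synth import gen_skeleton

from conftest import straight_skeleton_frame


@pytest.fixture(scope="module")
def S() -> mo.ScoringMatrix:
    return mo.ScoringMatrix.smooth_default()


def brute_force_nblast(query: mo.DotProps, target: mo.DotProps,
                       S: mo.ScoringMatrix) -> float:
    total = 0.0
    for p, t in zip(query.points, query.tangents):
        d = np.linalg.norm(target.points - p, axis=1)
        j = int(np.argmin(d))
        total += float(S.lookup(np.array([d[j]]),
                                np.array([abs(float(t @ target.tangents[j]))]))[0])
    return total


def jitter(dp: mo.DotProps, sigma: float, seed: int) -> mo.DotProps:
    rng = np.random.default_rng(seed)
    pts = dp.points + rng.normal(0, sigma, dp.points.shape)
    return mo.DotProps(pts, dp.tangents, source_id=dp.source_id + "_jit")


def random_dotprops(seed: int, n: int = 40, scale: float = 30.0) -> mo.DotProps:
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, scale, (n, 3))
    tg = rng.normal(size=(n, 3))
    tg /= np.linalg.norm(tg, axis=1, keepdims=True)
    return mo.DotProps(pts, tg, source_id=f"rand{seed}")


class TestRescale:
    def test_nm_to_um(self):
        sk = Skeleton(straight_skeleton_frame(3, step=8000.0), units="nm")
        out = mo.rescale_to_microns(sk)
        assert out.units == Units.um
        assert out.nodes["x"].tolist() == [0.0, 8.0, 16.0]

    def test_idempotent_on_um(self):
        sk = Skeleton(straight_skeleton_frame(3), units="um")
        out = mo.rescale_to_microns(sk)
        pd.testing.assert_frame_equal(out.nodes, sk.nodes)

    def test_round_trip(self):
        sk = Skeleton(straight_skeleton_frame(4, step=1234.5), units="nm")
        um = mo.rescale_to_microns(sk)
        back = um.nodes[["x", "y", "z", "radius"]] * 1000.0
        assert np.allclose(back, sk.nodes[["x", "y", "z", "radius"]])


class TestPrune:
    def test_short_twig_removed_long_retained(self):
        sk = gen_skeleton(1, n_branches=3, twig_lengths=(5.0, 20.0))
        pruned = mo.prune_short_neurites(sk, min_length=10.0)
        lengths = sorted(mo._path_length(pruned, p)
                         for p in mo._segment_paths(pruned))
        assert all(l >= 10.0 for l in lengths)
        assert any(np.isclose(l, 20.0) for l in lengths)
        assert pruned.n_nodes() == sk.n_nodes() - 5

    def test_unbranched_cable_unchanged(self):
        sk = Skeleton(straight_skeleton_frame(51), units="um")
        pruned = mo.prune_short_neurites(sk, min_length=10.0)
        assert pruned.n_nodes() == sk.n_nodes()

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_on_random_skeletons(self, seed):
        rng = np.random.default_rng(seed)
        twigs = tuple(float(x) for x in rng.uniform(2, 30, rng.integers(1, 5)))
        sk = gen_skeleton(seed, n_branches=1 + len(twigs), twig_lengths=twigs)
        once = mo.prune_short_neurites(sk)
        twice = mo.prune_short_neurites(once)
        pd.testing.assert_frame_equal(once.nodes, twice.nodes)
        assert twice.n_nodes() <= sk.n_nodes()
        twice.validate()  # still a tree

    def test_requires_micron_units(self):
        sk = Skeleton(straight_skeleton_frame(5), units="nm")
        with pytest.raises(ConfigError):
            mo.prune_short_neurites(sk)


class TestDotProps:
    def test_straight_cable_tangents_along_x(self):
        sk = Skeleton(straight_skeleton_frame(10), units="um")
        dp = mo.skeleton_to_dotprops(sk, k=5)
        assert np.allclose(np.abs(dp.tangents[:, 0]), 1.0, atol=1e-9)

    def test_deterministic_sign_convention(self):
        sk = Skeleton(straight_skeleton_frame(10), units="um")
        a = mo.skeleton_to_dotprops(sk, k=5)
        b = mo.skeleton_to_dotprops(sk, k=5)
        assert np.array_equal(a.tangents, b.tangents)
        assert (a.tangents[:, 0] > 0).all()  # first nonzero component positive

    def test_corner_tangents_match_eigen_oracle(self):
        # L-shape: 10 nodes along x then 10 along y
        n = 10
        pts = np.vstack([
            np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]),
            np.column_stack([np.full(n, n - 1.0), np.arange(1, n + 1), np.zeros(n)]),
        ])
        df = pd.DataFrame({
            "node_id": np.arange(1, 2 * n + 1),
            "parent_id": np.r_[-1, np.arange(1, 2 * n)],
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "radius": 0.1,
        })
        sk = Skeleton(df, units="um")
        k = 5
        dp = mo.skeleton_to_dotprops(sk, k=k)
        from scipy.spatial import cKDTree
        _, nn = cKDTree(pts).query(pts, k=k)
        for i in range(len(pts)):
            nb = pts[nn[i]] - pts[nn[i]].mean(axis=0)
            evals, evecs = np.linalg.eigh(nb.T @ nb)
            expect = evecs[:, -1]
            assert np.isclose(abs(dp.tangents[i] @ expect), 1.0, atol=1e-6)

    def test_too_few_nodes_suggests_smaller_k(self):
        sk = Skeleton(straight_skeleton_frame(3), units="um")
        with pytest.raises(ConfigError, match="smaller k"):
            mo.skeleton_to_dotprops(sk, k=5)


class TestScoringMatrix:
    def test_monotone_shape(self, S):
        assert (np.diff(S.scores, axis=0) <= 0).all()  # decays with distance
        assert (np.diff(S.scores, axis=1) >= 0).all()  # grows with |dot|

    def test_lookup_open_ended_last_bin(self, S):
        far = S.lookup(np.array([1e9]), np.array([0.5]))
        assert far[0] == S.scores[-1, S.scores.shape[1] // 2]

    def test_csv_round_trip(self, S, tmp_path):
        p = tmp_path / "scores.csv"
        S.to_csv(p)
        back = mo.read_scoring_matrix(p)
        assert np.allclose(back.scores, S.scores)
        assert np.allclose(back.dist_edges, S.dist_edges)
        assert np.allclose(back.dot_edges, S.dot_edges)


class TestNblast:
    def test_self_raw_is_zero_distance_parallel_sum(self, S):
        dp = random_dotprops(0)
        expect = len(dp) * float(S.lookup(np.zeros(1), np.ones(1))[0])
        assert mo.nblast_raw(dp, dp, S) == pytest.approx(expect)

    def test_two_point_hand_computation(self):
        S2 = mo.ScoringMatrix(np.array([0.0, 1.0]), np.array([0.0, 0.5, 1.0]),
                              np.array([[1.0, 2.0], [-1.0, 0.5]]))
        q = mo.DotProps(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                        np.array([[1.0, 0, 0], [0.0, 1, 0]]))
        t = mo.DotProps(np.array([[0.5, 0, 0], [3.0, 0, 0]]),
                        np.array([[1.0, 0, 0], [1.0, 0, 0]]))
        # q0 -> t0: dist 0.5, |dot| 1  -> bin (0, hi) = 2.0
        # q1 -> t1: dist 0,   |dot| 0  -> bin (0, lo) = 1.0
        assert mo.nblast_raw(q, t, S2) == pytest.approx(3.0)
        # reverse: t0 -> q0 dist 0.5 dot 1 -> 2.0 ; t1 -> q1 dist 0 dot 0 -> 1.0
        assert mo.nblast_raw(t, q, S2) == pytest.approx(3.0)

    def test_asymmetry_witnessed(self, S):
        q = random_dotprops(1, n=10)
        t = random_dotprops(2, n=60)
        assert mo.nblast_raw(q, t, S) != pytest.approx(mo.nblast_raw(t, q, S))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_nearest_neighbor(self, S, seed):
        rng = np.random.default_rng(seed)
        q = random_dotprops(seed * 2 + 10, n=int(rng.integers(5, 200)))
        t = random_dotprops(seed * 2 + 11, n=int(rng.integers(5, 200)))
        assert mo.nblast_raw(q, t, S) == pytest.approx(
            brute_force_nblast(q, t, S), abs=1e-9)

    def test_normalized_self_is_exactly_one(self, S):
        dp = random_dotprops(3)
        assert mo.nblast_normalized(dp, dp, S) == 1.0

    def test_duplicate_scores_one(self, S):
        dp = random_dotprops(4)
        dup = mo.DotProps(dp.points.copy(), dp.tangents.copy(), "copy")
        assert mo.nblast_normalized(dp, dup, S) == pytest.approx(1.0)

    def test_self_maximality(self, S):
        dp = random_dotprops(5)
        dup = mo.DotProps(dp.points.copy(), dp.tangents.copy(), "copy")
        s_dup = mo.nblast_raw(dp, dup, S)
        for seed in range(5):
            other = random_dotprops(50 + seed)
            assert mo.nblast_raw(dp, other, S) <= s_dup

    def test_empty_rejected(self, S):
        with pytest.raises(ValidationError):
            mo.DotProps(np.empty((0, 3)), np.empty((0, 3)))


class TestRanking:
    def test_pooled_dedup_and_self_removal(self):
        hits_a = {"c": 0.9, "q2": 0.95, "d": 0.5}
        hits_b = {"c": 0.8, "e": 0.6}
        rep = mo.rank_top_matches(hits_a, hits_b, ("q1", "q2"), n=5)
        ids = rep.table["candidate_id"].tolist()
        assert ids == ["c", "e", "d"]
        assert rep.table.loc[0, "score"] == 0.9  # best of both hits for c

    def test_ties_broken_by_id(self):
        rep = mo.rank_top_matches({"b": 0.5, "a": 0.5}, {}, ("q", "q2"), n=2)
        assert rep.table["candidate_id"].tolist() == ["a", "b"]

    def test_matches_sort_merge_oracle(self):
        rng = np.random.default_rng(7)
        cands = [f"c{i}" for i in range(20)]
        hits_a = {c: float(rng.random()) for c in cands[:15]}
        hits_b = {c: float(rng.random()) for c in cands[5:]}
        rep = mo.rank_top_matches(hits_a, hits_b, ("qa", "qb"), n=5)
        pooled = {c: max(hits_a.get(c, -np.inf), hits_b.get(c, -np.inf))
                  for c in set(hits_a) | set(hits_b)}
        oracle = sorted(pooled, key=lambda c: (-pooled[c], c))[:5]
        assert rep.table["candidate_id"].tolist() == oracle

    def test_invalid_n(self):
        with pytest.raises(ConfigError):
            mo.rank_top_matches({}, {}, ("a", "b"), n=0)


class TestMatchTypes:
    def test_exact_copy_ranks_first_with_one(self, S):
        q = random_dotprops(8)
        targets = {"copy": mo.DotProps(q.points.copy(), q.tangents.copy()),
                   "noise": random_dotprops(80)}
        reports = mo.match_types({"q": q}, targets, S)
        top = reports["q"].table.iloc[0]
        assert top["candidate_id"] == "copy"
        assert top["normalized"] == pytest.approx(1.0)

    def test_jittered_copy_beats_decoys(self, S):
        q = random_dotprops(9)
        targets = {f"decoy{i}": random_dotprops(200 + i) for i in range(10)}
        targets["jit"] = jitter(q, 0.5, 1)
        reports = mo.match_types({"q": q}, targets, S)
        assert reports["q"].table.iloc[0]["candidate_id"] == "jit"

    def test_top_n_larger_than_pool(self, S):
        q = random_dotprops(10)
        targets = {"a": random_dotprops(11), "b": random_dotprops(12)}
        reports = mo.match_types({"q": q}, targets, S, top_n=10)
        assert len(reports["q"].table) == 2

    def test_empty_targets_rejected(self, S):
        with pytest.raises(ValidationError):
            mo.match_types({"q": random_dotprops(13)}, {}, S)


class TestPipelineOrder:
    def test_rescale_then_prune_equals_prune_scaled(self):
        sk_um = gen_skeleton(4, n_branches=3, twig_lengths=(4.0, 25.0))
        nodes_nm = sk_um.nodes.copy()
        nodes_nm[["x", "y", "z", "radius"]] *= 1000.0
        sk_nm = Skeleton(nodes_nm, units="nm")
        a = mo.prune_short_neurites(mo.rescale_to_microns(sk_nm), 10.0)
        b = mo.prune_short_neurites(sk_um, 10.0)
        assert np.allclose(a.coords(), b.coords())
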