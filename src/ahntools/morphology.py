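"""Skeleton preprocessing and NBLAST-style morphology similarity scoring.

NBLAST reduces each neuron to a cloud of points with local tangent vectors
(dotprops).  A query is scored against a target by finding, for every query
point, the nearest target point and looking up a log-odds score indexed by
their Euclidean distance and the absolute dot product of their tangents;
the raw score is the sum over query points and is asymmetric in
(query, target).  Normalizing by the query's self-score maps a perfect
match to 1.  Before conversion, skeletons are rescaled to microns and
terminal twigs shorter than 10 μm are pruned to a fixed point, suppressing
spurious short projections left by automated skeletonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import ConfigError, Skeleton, Units, ValidationError

NM_PER_UM = 1000.0


# -- preprocessing ----------------------------------------------------------

def rescale_to_microns(skeleton: Skeleton, nm_per_unit: float = 1.0) -> Skeleton:
    """Convert a skeleton's coordinates and radii to microns.

    nm-flagged skeletons are divided by 1000 (after applying
    ``nm_per_unit`` for volumes whose raw unit is a multiple of a
    nanometre, e.g. EM voxel pitch); μm-flagged skeletons pass through
    unchanged.
    """
    if skeleton.units == Units.um:
        return skeleton.copy()
    if skeleton.units != Units.nm:
        raise ConfigError(f"unknown units {skeleton.units!r}")
    out = skeleton.copy()
    factor = nm_per_unit / NM_PER_UM
    out.nodes[["x", "y", "z", "radius"]] *= factor
    out.units = Units.um
    return out


def _segment_paths(skeleton: Skeleton) -> list[list[int]]:
    """Terminal segments: each leaf back to (excluding) the nearest branch
    point or root.  The path includes the leaf and every intermediate
    slab node."""
    children = skeleton.children_map()
    parent = dict(zip(skeleton.nodes["node_id"].astype(int),
                      skeleton.nodes["parent_id"].astype(int)))
    root = skeleton.root
    leaves = [n for n, ch in children.items() if not ch]
    segs = []
    for leaf in leaves:
        path = [leaf]
        cur = parent[leaf]
        while cur != -1 and len(children[cur]) == 1 and cur != root:
            path.append(cur)
            cur = parent[cur]
        segs.append(path)
    return segs


def _path_length(skeleton: Skeleton, path: list[int]) -> float:
    """Cable length of a leaf-to-branch-point segment, including the final
    edge from the last slab node to its (branch-point) parent."""
    xyz = skeleton.nodes.set_index(skeleton.nodes["node_id"].astype(int))[["x", "y", "z"]]
    parent = dict(zip(skeleton.nodes["node_id"].astype(int),
                      skeleton.nodes["parent_id"].astype(int)))
    total = 0.0
    for nid in path:
        pid = parent[nid]
        if pid == -1:
            continue
        total += float(np.linalg.norm(xyz.loc[nid].to_numpy() - xyz.loc[pid].to_numpy()))
    return total


def prune_short_neurites(skeleton: Skeleton, min_length: float = 10.0) -> Skeleton:
    """Iteratively remove terminal twigs shorter than ``min_length`` μm.

    A twig is the cable from a leaf back to the nearest branch point;
    twigs whose path length is below the bound are deleted, and the
    process repeats (removing a twig can expose a new sub-threshold
    twig) until a fixed point — pruning is idempotent.  An unbranched
    skeleton has no twigs and passes through.  If pruning would delete
    everything, the longest root-to-leaf path is returned with a
    warning.
    """
    if skeleton.units != Units.um:
        raise ConfigError("prune_short_neurites expects a μm skeleton; rescale first")
    current = skeleton.copy()
    while True:
        children = current.children_map()
        has_branch = any(len(ch) > 1 for ch in children.values())
        if not has_branch:
            # a bare cable is the protected main path, never pruned
            return current
        doomed: set[int] = set()
        for path in _segment_paths(current):
            if _path_length(current, path) < min_length:
                doomed.update(path)
        if not doomed:
            return current
        keep = current.nodes.loc[~current.nodes["node_id"].astype(int).isin(doomed)]
        if len(keep) == 0 or not (keep["parent_id"] == -1).any():
            warnings.warn(
                "pruning would delete the entire skeleton; "
                "returning the longest root-to-leaf path", stacklevel=2)
            return _longest_root_leaf_path(skeleton)
        current = Skeleton(keep.reset_index(drop=True), units=current.units,
                           skeleton_id=current.skeleton_id)


def _longest_root_leaf_path(skeleton: Skeleton) -> Skeleton:
    children = skeleton.children_map()
    parent = dict(zip(skeleton.nodes["node_id"].astype(int),
                      skeleton.nodes["parent_id"].astype(int)))
    xyz = skeleton.nodes.set_index(skeleton.nodes["node_id"].astype(int))[["x", "y", "z"]]
    leaves = [n for n, ch in children.items() if not ch]
    best_path, best_len = [skeleton.root], -1.0
    for leaf in leaves:
        path, cur, length = [], leaf, 0.0
        while cur != -1:
            path.append(cur)
            pid = parent[cur]
            if pid != -1:
                length += float(np.linalg.norm(
                    xyz.loc[cur].to_numpy() - xyz.loc[pid].to_numpy()))
            cur = pid
        if length > best_len:
            best_len, best_path = length, path
    keep = skeleton.nodes.loc[skeleton.nodes["node_id"].astype(int).isin(best_path)]
    return Skeleton(keep.reset_index(drop=True), units=skeleton.units,
                    skeleton_id=skeleton.skeleton_id)


# -- dotprops ---------------------------------------------------------------

@dataclass
class DotProps:
    """Point cloud plus unit tangent vectors — the NBLAST input form."""

    points: np.ndarray
    tangents: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValidationError("points must be a non-empty N×3 array")
        if self.tangents.shape != self.points.shape:
            raise ValidationError("tangents must match points in shape")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("tangents must be unit length")

    def __len__(self) -> int:
        return len(self.points)


def _canonical_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip each vector so its first nonzero component is positive."""
    out = vecs.copy()
    for i, v in enumerate(out):
        for c in v:
            if c != 0:
                if c < 0:
                    out[i] = -v
                break
    return out


def skeleton_to_dotprops(skeleton: Skeleton, k: int = 5) -> DotProps:
    """Reduce a skeleton to points with local principal-direction tangents.

    The tangent at each node is the dominant eigenvector of the
    covariance of its k nearest nodes (including itself); signs are
    canonicalized for determinism, which is harmless because scoring
    uses |dot|.
    """
    pts = skeleton.coords()
    n = len(pts)
    if n < k:
        raise ConfigError(f"skeleton has {n} nodes < k={k}; use a smaller k")
    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=k)
    tangents = np.empty_like(pts)
    for i in range(n):
        nb = pts[nn[i]]
        centred = nb - nb.mean(axis=0)
        # dominant right singular vector == largest-eigenvalue direction
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        tangents[i] = vt[0]
    tangents = _canonical_sign(tangents)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return DotProps(pts, tangents, source_id=skeleton.skeleton_id)


# -- scoring matrix ---------------------------------------------------------

@dataclass
class ScoringMatrix:
    """Log-odds lookup indexed by (distance bin, |tangent dot| bin).

    ``dist_edges``: increasing interior bin edges in μm starting at 0;
    the final bin is open-ended.  ``dot_edges``: interior edges in
    [0, 1].  ``scores``: (len(dist_edges)) × (len(dot_edges)) table —
    edges here are the FULL ascending edge arrays including 0 (and 1 for
    dots), so bin i spans [edges[i], edges[i+1]).
    """

    dist_edges: np.ndarray
    dot_edges: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.dist_edges = np.asarray(self.dist_edges, dtype=float)
        self.dot_edges = np.asarray(self.dot_edges, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (np.all(np.diff(self.dist_edges) > 0) and self.dist_edges[0] == 0):
            raise ConfigError("distance edges must start at 0 and increase")
        if not (np.all(np.diff(self.dot_edges) > 0)
                and self.dot_edges[0] == 0 and self.dot_edges[-1] == 1):
            raise ConfigError("dot-product edges must ascend from 0 to 1")
        expected = (len(self.dist_edges), len(self.dot_edges) - 1)
        if self.scores.shape != expected:
            raise ConfigError(
                f"scores shape {self.scores.shape} != {expected} "
                "(one distance row per edge incl. open-ended last bin)")

    def lookup(self, dist: np.ndarray, absdot: np.ndarray) -> np.ndarray:
        di = np.searchsorted(self.dist_edges, dist, side="right") - 1
        di = np.clip(di, 0, self.scores.shape[0] - 1)
        aj = np.searchsorted(self.dot_edges, absdot, side="right") - 1
        aj = np.clip(aj, 0, self.scores.shape[1] - 1)
        return self.scores[di, aj]

    @classmethod
    def smooth_default(cls, max_dist: float = 50.0, n_dist: int = 21,
                       n_dot: int = 10, length_scale: float = 5.0) -> "ScoringMatrix":
        """Smooth synthetic log-odds surface: decaying in distance,
        increasing in |dot|, positive near (0, 1) and negative far away.
        A stand-in with the qualitative shape of trained fly-neuron
        matrices; real trained values load via :func:`read_scoring_matrix`."""
        dist_edges = np.linspace(0, max_dist, n_dist)
        dot_edges = np.linspace(0, 1, n_dot + 1)
        width = dist_edges[1] - dist_edges[0]
        dmid = dist_edges + width / 2
        amid = (dot_edges[:-1] + dot_edges[1:]) / 2
        surf = 4.0 * np.exp(-dmid[:, None] / length_scale) * amid[None, :] - 0.5
        return cls(dist_edges, dot_edges, surf)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores,
                          index=[f"{e:g}" for e in self.dist_edges],
                          columns=[f"{a:g}-{b:g}" for a, b in
                                   zip(self.dot_edges[:-1], self.dot_edges[1:])])
        df.index.name = "dist_lower"
        df.to_csv(path)


def read_scoring_matrix(path: str | Path) -> ScoringMatrix:
    """Load a scoring matrix CSV (rows = distance-bin lower edges,
    columns = ``lo-hi`` dot bins)."""
    df = pd.read_csv(path, index_col=0)
    dist_edges = df.index.to_numpy(dtype=float)
    lowers = [float(c.split("-")[0]) for c in df.columns]
    uppers = [float(c.split("-")[1]) for c in df.columns]
    dot_edges = np.array(lowers + [uppers[-1]], dtype=float)
    return ScoringMatrix(dist_edges, dot_edges, df.to_numpy(dtype=float))


# -- scoring ----------------------------------------------------------------

def nblast_raw(query: DotProps, target: DotProps, S: ScoringMatrix) -> float:
    """Raw NBLAST score of query against target (asymmetric).

    For each query point the Euclidean-nearest target point is found
    (k-d tree; identical to exhaustive search), and S(distance,
    |tangent·tangent|) summed over query points.
    """
    if len(query) == 0 or len(target) == 0:
        raise ValidationError("dotprops must be non-empty")
    tree = cKDTree(target.points)
    dist, idx = tree.query(query.points, k=1)
    absdot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[idx]))
    absdot = np.clip(absdot, 0.0, 1.0)
    return float(S.lookup(dist, absdot).sum())


def nblast_normalized(query: DotProps, target: DotProps, S: ScoringMatrix) -> float:
    """Raw score divided by the query's self-score; self-comparison is 1."""
    self_score = nblast_raw(query, query, S)
    if self_score <= 0:
        raise ValidationError(
            f"non-positive self-score {self_score}; degenerate scoring matrix")
    return nblast_raw(query, target, S) / self_score


# -- ranking and matching ---------------------------------------------------

@dataclass
class MatchReport:
    """Ranked candidate matches for one query (or query pair)."""

    query_id: str
    table: pd.DataFrame  # columns: candidate_id, raw, normalized, mean_normalized

    def top(self, n: int) -> pd.DataFrame:
        return self.table.head(n)

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.table["candidate_id"])


def _rank(df: pd.DataFrame, score_col: str) -> pd.DataFrame:
    return df.sort_values([score_col, "candidate_id"],
                          ascending=[False, True], kind="stable").reset_index(drop=True)


def rank_top_matches(
    hits_a: dict[str, float],
    hits_b: dict[str, float],
    query_ids: tuple[str, str],
    n: int = 5,
) -> MatchReport:
    """Pool two cells' hit lists into one ranked report for the pair.

    Candidates matching either query are dropped (self-matches), a
    candidate hit by both cells is kept once at its better score, and
    the top n by score are returned with ties broken by candidate id.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    pooled: dict[str, float] = {}
    for hits in (hits_a, hits_b):
        for cand, score in hits.items():
            if cand in query_ids:
                continue
            if cand not in pooled or score > pooled[cand]:
                pooled[cand] = score
    df = pd.DataFrame({"candidate_id": list(pooled), "score": list(pooled.values())})
    df = df.sort_values(["score", "candidate_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return MatchReport("+".join(query_ids), df.head(n))


def match_types(
    queries: dict[str, DotProps],
    targets: dict[str, DotProps],
    S: ScoringMatrix,
    top_n: int = 10,
) -> dict[str, MatchReport]:
    """Rank every target against every query by normalized NBLAST score.

    Ranking uses the forward query-normalized score; the mean of forward
    and reverse normalized scores is reported alongside.  Self-ids are
    excluded.  Returns one MatchReport per query with the top_n
    candidates (the full pool if smaller).
    """
    if not targets:
        raise ValidationError("empty target set")
    self_scores = {qid: nblast_raw(q, q, S) for qid, q in queries.items()}
    tgt_self = {tid: nblast_raw(t, t, S) for tid, t in targets.items()}
    reports = {}
    for qid, q in queries.items():
        if self_scores[qid] <= 0:
            raise ValidationError(f"non-positive self-score for {qid}")
        rows = []
        for tid, t in targets.items():
            if tid == qid:
                continue
            fwd_raw = nblast_raw(q, t, S)
            fwd = fwd_raw / self_scores[qid]
            rev = nblast_raw(t, q, S) / tgt_self[tid] if tgt_self[tid] > 0 else np.nan
            rows.append((tid, fwd_raw, fwd, (fwd + rev) / 2))
        df = pd.DataFrame(rows, columns=["candidate_id", "raw", "normalized",
                                         "mean_normalized"])
        reports[qid] = MatchReport(qid, _rank(df, "normalized").head(top_n))
    return reports
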