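"""Marker-based candidate selection, CPM-log2 normalization and panel clustering.

Candidate ascending histaminergic neurons are picked out of a single-cell
count matrix by a raw-count marker filter: the cell must express the
histamine-synthesis gene (Hdc-like) and exactly one of two Hox genes
(Antp-like marks the mesothoracic pair, Ubx-like the metathoracic pair),
with the dominant Hox at least 15-fold above the other.  Expression is
then normalized to counts per million with log2(n+1) scaling, and gene
panels are displayed via complete-linkage hierarchical clustering on
Euclidean distance of both genes and cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .model import ConfigError, ValidationError


@dataclass
class ExpressionMatrix:
    """Cells × genes raw integer counts, with an optional derived view.

    ``raw`` is primary; ``normalized`` (if present) is always derived
    from it and tagged with the normalization applied.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    normalization: str | None = None

    def __post_init__(self) -> None:
        vals = self.raw.to_numpy()
        if (vals < 0).any():
            raise ValidationError("raw counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("raw counts must be integers")

    @property
    def cells(self) -> list[str]:
        return list(self.raw.index)

    @property
    def genes(self) -> list[str]:
        return list(self.raw.columns)


@dataclass(frozen=True)
class CandidateCall:
    """Outcome of the marker filter for one cell."""

    cell_id: str
    label: str  # "MsAHN-like" | "MtAHN-like" | "rejected"
    reason: str
    hdc: int
    antp: int
    ubx: int
    dominance_ratio: float  # inf when the minor Hox count is 0


MS_LABEL = "MsAHN-like"
MT_LABEL = "MtAHN-like"
REJECTED = "rejected"


def select_candidates(
    em: ExpressionMatrix,
    marker_genes: tuple[str, str, str] = ("Hdc", "Antp", "Ubx"),
    min_count: int = 2,
    dominance: float = 15.0,
    cell_whitelist: list[str] | None = None,
) -> list[CandidateCall]:
    """Apply the raw-count marker filter to every cell.

    A cell passes iff its Hdc-like count is >= ``min_count``, the larger
    Hox count is >= ``min_count``, and dominant:other ratio is >=
    ``dominance`` (a zero minor count passes — the ratio is infinite).
    Equal Hox counts reject the cell.  Antp-dominant cells are labeled
    MsAHN-like, Ubx-dominant MtAHN-like.  ``cell_whitelist`` restricts
    the filter to an upstream cell selection (e.g. an atlas cluster
    assignment) instead of the whole matrix.
    """
    hdc_g, antp_g, ubx_g = marker_genes
    missing = [g for g in marker_genes if g not in em.raw.columns]
    if missing:
        raise ConfigError(f"marker genes absent from matrix: {missing}")
    cells = (em.raw.index if cell_whitelist is None
             else [c for c in em.raw.index if c in set(cell_whitelist)])
    calls = []
    for cell in cells:
        hdc = int(em.raw.at[cell, hdc_g])
        antp = int(em.raw.at[cell, antp_g])
        ubx = int(em.raw.at[cell, ubx_g])
        dom, minor = max(antp, ubx), min(antp, ubx)
        ratio = float("inf") if minor == 0 else dom / minor
        if hdc < min_count:
            call = (REJECTED, f"Hdc-like count {hdc} < {min_count}")
        elif antp == ubx:
            call = (REJECTED, "Hox counts tied; no dominant gene")
        elif dom < min_count:
            call = (REJECTED, f"dominant Hox count {dom} < {min_count}")
        elif ratio < dominance:
            call = (REJECTED, f"dominance ratio {ratio:.3g} < {dominance:g}")
        else:
            call = (MS_LABEL if antp > ubx else MT_LABEL, "passed")
        calls.append(CandidateCall(cell, call[0], call[1], hdc, antp, ubx, ratio))
    return calls


def candidate_ids(calls: list[CandidateCall]) -> dict[str, list[str]]:
    """Passing cells grouped by label."""
    out: dict[str, list[str]] = {MS_LABEL: [], MT_LABEL: []}
    for c in calls:
        if c.label != REJECTED:
            out[c.label].append(c.cell_id)
    return out


def cpm_log2(em: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization followed by log2(n + 1) scaling.

    value(c, g) = log2(raw(c, g) * 1e6 / total(c) + 1).  Cells with zero
    total count are excluded with a warning.
    """
    totals = em.raw.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-total cell(s) excluded from "
                      "normalization", stacklevel=2)
    raw = em.raw.loc[~zero]
    cpm = raw.div(totals[~zero], axis=0) * 1e6
    norm = np.log2(cpm + 1.0)
    return ExpressionMatrix(raw=raw, normalized=norm, normalization="cpm_log2")


# -- complete-linkage clustering --------------------------------------------
#
# The agglomeration is written out rather than delegated so that
# equal-distance merges resolve canonically (smallest member label first),
# making dendrograms invariant to input row order.  Output follows the
# scipy linkage-matrix convention, so scipy's dendrogram/tree utilities
# apply downstream.

def complete_linkage(points: np.ndarray, labels: list[str]) -> np.ndarray:
    """O(n³) complete-linkage agglomeration with canonical tie-breaking.

    Returns an (n-1) × 4 scipy-style linkage matrix.  Among merges at
    the minimal distance, the pair whose lexicographically smallest
    member labels come first wins.
    """
    n = len(points)
    if n < 2:
        raise ConfigError("clustering needs at least 2 items")
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    # active cluster id -> (member original indices, min member label)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    keyof = {i: sorted(labels[j] for j in clusters[i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), dij in dist.items():
            key = (dij, min(keyof[i], keyof[j]), max(keyof[i], keyof[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j)]
        # canonical child order: the cluster holding the smallest label first,
        # so dendrogram leaf order is invariant to input row order
        first, second = (i, j) if keyof[i] <= keyof[j] else (j, i)
        Z[step] = [first, second, dij, len(clusters[i]) + len(clusters[j])]
        members = clusters.pop(i) + clusters.pop(j)
        clusters[next_id] = members
        keyof[next_id] = sorted(keyof[i] + keyof[j])
        del keyof[i], keyof[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for other in clusters:
            if other == next_id:
                continue
            dmax = max(d[a, b] for a in members for b in clusters[other])
            dist[(min(other, next_id), max(other, next_id))] = dmax
        next_id += 1
    return Z


def leaf_order(Z: np.ndarray) -> list[int]:
    """Left-to-right leaf order induced by a linkage matrix."""
    tree = to_tree(Z)
    return tree.pre_order(lambda leaf: leaf.id)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Export a linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass
class PanelClustering:
    """Gene and cell dendrograms for one gene panel plus the ordered table."""

    gene_linkage: np.ndarray
    cell_linkage: np.ndarray
    gene_labels: list[str]  # in linkage (input) order
    cell_labels: list[str]
    gene_order: list[str]  # dendrogram leaf order
    cell_order: list[str]
    heatmap: pd.DataFrame  # normalized values, rows=cells, cols=genes, both ordered

    def gene_newick(self) -> str:
        return linkage_to_newick(self.gene_linkage, self.gene_labels)

    def cell_newick(self) -> str:
        return linkage_to_newick(self.cell_linkage, self.cell_labels)


def cluster_panel(
    em: ExpressionMatrix,
    gene_panel: list[str],
    linkage: str = "complete",
    metric: str = "euclidean",
) -> PanelClustering:
    """Hierarchically cluster a gene panel and the cells over it.

    Both genes and cells are agglomerated with complete linkage on
    Euclidean distance of the normalized expression values; the heatmap
    table is reordered by the two dendrograms' leaf orders.
    """
    if linkage != "complete" or metric != "euclidean":
        raise ConfigError("only complete linkage on Euclidean distance is supported")
    if em.normalized is None:
        raise ConfigError("cluster_panel requires a normalized matrix (run cpm_log2)")
    missing = [g for g in gene_panel if g not in em.normalized.columns]
    if missing:
        raise ConfigError(f"panel genes absent from matrix: {missing}")
    if len(gene_panel) < 2:
        raise ConfigError("gene panel must contain at least 2 genes")
    if len(em.normalized) < 2:
        raise ConfigError("need at least 2 cells to cluster")
    sub = em.normalized[list(gene_panel)]
    cells = list(sub.index)
    genes = list(sub.columns)
    Zc = complete_linkage(sub.to_numpy(), cells)
    Zg = complete_linkage(sub.to_numpy().T, genes)
    corder = [cells[i] for i in leaf_order(Zc)]
    gorder = [genes[i] for i in leaf_order(Zg)]
    return PanelClustering(Zg, Zc, genes, cells, gorder, corder,
                           sub.loc[corder, gorder])
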