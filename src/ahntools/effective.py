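"""Group-collapsed connectivity, input fractions, and 2-step effective strength.

Effective connection strength asks how strongly a source cell type drives a
target type through exactly one intermediary: for every allowed intermediary
group m, the fraction of m's total synaptic input contributed by the source
is multiplied by the fraction of the target's total input contributed by m,
and the products are summed.  Descending and sensory groups are excluded as
intermediaries — they receive their drive outside the network under study —
as are the source and target groups themselves.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CellClass, ConfigError, NeuronTable, RoiCount, SynapseEdge

#: GroupMatrix.mode values
MODE_WEIGHTS = "weights"
MODE_FRACTIONS = "fractions"
MODE_EFFECTIVE = "effective"


@dataclass
class GroupMatrix:
    """Dense group-by-group connectivity matrix with a mode tag.

    ``matrix`` rows are source groups, columns target groups.  The mode
    distinguishes raw synapse weights, per-column input fractions, and
    2-step effective strengths.
    """

    matrix: pd.DataFrame
    mode: str = MODE_WEIGHTS

    def __post_init__(self) -> None:
        if self.mode not in (MODE_WEIGHTS, MODE_FRACTIONS, MODE_EFFECTIVE):
            raise ConfigError(f"unknown GroupMatrix mode {self.mode!r}")
        if (self.matrix.to_numpy() < 0).any():
            raise ConfigError("GroupMatrix entries must be non-negative")

    @property
    def sources(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def targets(self) -> list[str]:
        return list(self.matrix.columns)

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: source, target, value."""
        long = self.matrix.stack().rename("value").reset_index()
        long.columns = ["source", "target", "value"]
        return long


def collapse_by_group(
    edges: list[SynapseEdge],
    grouping: dict[str, str],
) -> GroupMatrix:
    """Sum synapse weights over a neuron -> group mapping.

    Entry (g, h) is the total weight over all edges from members of g to
    members of h.  Every neuron appearing in the edge list must be
    mapped; unmapped ids raise with the offending list.
    """
    unmapped = sorted(({e.pre_id for e in edges} | {e.post_id for e in edges})
                      - set(grouping))
    if unmapped:
        raise ConfigError(f"neurons missing from grouping: {unmapped[:20]}"
                          + ("..." if len(unmapped) > 20 else ""))
    groups = sorted(set(grouping.values()))
    idx = {g: i for i, g in enumerate(groups)}
    mat = np.zeros((len(groups), len(groups)), dtype=float)
    for e in edges:
        mat[idx[grouping[e.pre_id]], idx[grouping[e.post_id]]] += e.weight
    return GroupMatrix(pd.DataFrame(mat, index=groups, columns=groups), MODE_WEIGHTS)


def to_input_fractions(gm: GroupMatrix) -> GroupMatrix:
    """Normalize each column of a weight matrix by its own sum.

    Column (target) sums become 1; all-zero columns stay zero with a
    warning.  The denominator is the group's entire collapsed input, so
    fractions reflect the whole connectome, not any analysis subset.
    """
    if gm.mode != MODE_WEIGHTS:
        raise ConfigError(f"expected a weights matrix, got mode {gm.mode!r}")
    mat = gm.matrix.to_numpy(dtype=float)
    colsums = mat.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} group(s) receive no input; fraction columns left zero",
            stacklevel=2,
        )
    out = np.divide(mat, np.where(zero, 1.0, colsums), where=True)
    return GroupMatrix(pd.DataFrame(out, index=gm.matrix.index, columns=gm.matrix.columns),
                       MODE_FRACTIONS)


def effective_strength(
    fractions: GroupMatrix,
    source_groups: list[str],
    target_groups: list[str],
    group_classes: dict[str, CellClass] | None = None,
    excluded_intermediary_classes: frozenset = frozenset({CellClass.DN, CellClass.SN,
                                                          CellClass.ASN}),
) -> GroupMatrix:
    """Path-length-2 effective connection strength between group sets.

    E(s, t) = sum over allowed intermediaries m of F(s -> m) * F(m -> t),
    where F is the input-fraction matrix.  Intermediaries exclude the
    sources and targets themselves and any group whose cell class is in
    ``excluded_intermediary_classes`` (descending and sensory by
    default).  Entries are bounded by [0, 1] since each factor is an
    input fraction.
    """
    if fractions.mode != MODE_FRACTIONS:
        raise ConfigError(f"expected an input-fraction matrix, got {fractions.mode!r}")
    overlap = set(source_groups) & set(target_groups)
    if overlap:
        raise ConfigError(f"source and target groups overlap: {sorted(overlap)}")
    all_groups = set(fractions.matrix.index)
    for name, gs in (("source", source_groups), ("target", target_groups)):
        missing = sorted(set(gs) - all_groups)
        if missing:
            raise ConfigError(f"{name} groups not in matrix: {missing}")
    group_classes = group_classes or {}
    barred = set(source_groups) | set(target_groups)
    allowed = [
        g for g in fractions.matrix.index
        if g not in barred
        and group_classes.get(g) not in excluded_intermediary_classes
    ]
    F = fractions.matrix
    # E = F[sources, allowed] @ F[allowed, targets]
    eff = F.loc[source_groups, allowed].to_numpy() @ F.loc[allowed, target_groups].to_numpy()
    return GroupMatrix(pd.DataFrame(eff, index=list(source_groups),
                                    columns=list(target_groups)), MODE_EFFECTIVE)


# -- ROI polarity profiles --------------------------------------------------

DEFAULT_SIDE_PATTERN = r"[_ ]?\((?:L|R)\)$|[_ ](?:L|R)$"


def _merge_side(roi: str, pattern: str) -> str:
    return re.sub(pattern, "", roi)


def roi_polarity_profile(
    rois: list[RoiCount],
    neurons: NeuronTable,
    type_of: dict[str, str] | None = None,
    zero_mn_presynaptic: bool = True,
    side_pattern: str = DEFAULT_SIDE_PATTERN,
) -> pd.DataFrame:
    """Per-type mean normalized pre/postsynaptic ROI profiles.

    Left/right ROI counts are merged by base name (trailing ``_L``/``_R``
    or `` (L)``/`` (R)``, configurable regex), each neuron's pre and post
    count vectors are normalized to sum 1, and the per-neuropil mean is
    taken over neurons of the same type.  Motor-neuron presynaptic
    counts are forced to zero before normalization when the flag is set
    (their presynaptic annotations in EM are unreliable).  Neurons with
    zero counts in both polarities are excluded with a warning.

    Returns a long DataFrame: type, roi, pre_fraction, post_fraction.
    """
    if type_of is None:
        type_of = {r.neuron_id: (r.type_label or r.cell_class.value) for r in neurons}
    df = pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in rois],
            "roi": [_merge_side(r.roi, side_pattern) for r in rois],
            "pre": [r.pre_count for r in rois],
            "post": [r.post_count for r in rois],
        }
    )
    if zero_mn_presynaptic:
        mn = {r.neuron_id for r in neurons if r.cell_class == CellClass.MN}
        df.loc[df["neuron_id"].isin(mn), "pre"] = 0
    merged = df.groupby(["neuron_id", "roi"], as_index=False)[["pre", "post"]].sum()
    profiles = []
    for nid, sub in merged.groupby("neuron_id"):
        pre_tot, post_tot = sub["pre"].sum(), sub["post"].sum()
        if pre_tot == 0 and post_tot == 0:
            warnings.warn(f"neuron {nid} has zero synaptic sites in all ROIs; excluded",
                          stacklevel=2)
            continue
        sub = sub.assign(
            pre_frac=sub["pre"] / pre_tot if pre_tot > 0 else 0.0,
            post_frac=sub["post"] / post_tot if post_tot > 0 else 0.0,
            type=type_of.get(nid, "untyped"),
        )
        profiles.append(sub)
    if not profiles:
        return pd.DataFrame(columns=["type", "roi", "pre_fraction", "post_fraction"])
    allp = pd.concat(profiles, ignore_index=True)
    # mean over the neurons of a type; a neuron absent from an ROI counts as 0
    wide_pre = allp.pivot_table(index="neuron_id", columns="roi", values="pre_frac",
                                fill_value=0.0)
    wide_post = allp.pivot_table(index="neuron_id", columns="roi", values="post_frac",
                                 fill_value=0.0)
    types = pd.Series({nid: type_of.get(nid, "untyped") for nid in wide_pre.index})
    out = []
    for t, ids in types.groupby(types).groups.items():
        pre_mean = wide_pre.loc[list(ids)].mean(axis=0)
        post_mean = wide_post.loc[list(ids)].mean(axis=0)
        for roi in wide_pre.columns:
            out.append((t, roi, pre_mean[roi], post_mean[roi]))
    return pd.DataFrame(out, columns=["type", "roi", "pre_fraction", "post_fraction"])
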