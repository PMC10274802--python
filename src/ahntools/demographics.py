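"""Synapse-count thresholding and upstream/downstream partner demographics.

Connectome reconstructions differ in completeness, so a fixed synapse-count
threshold in one volume must be rescaled before it is comparable in another:
the scaling uses the ratio of total connection counts onto the same focal
cells in the two volumes.  Above threshold, partners are summarized by cell
class (synapse fractions), by descending-neuron type (with a pooled
remainder), and by which subset of the focal cells they contact (the
shared-input partition behind convergent-input graph plots).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    CellClass,
    ConfigError,
    FRAGMENT_CLASSES,
    NeuronTable,
    SynapseEdge,
    SynapseSite,
    ValidationError,
)

logger = logging.getLogger(__name__)


def apply_threshold(
    edges: list[SynapseEdge],
    threshold: int,
    focal_ids: set[str] | list[str],
    only_focal: bool = True,
) -> list[SynapseEdge]:
    """Drop focal-incident edges whose summed synapse count is below threshold.

    The threshold applies to the aggregate per-pair weight and is
    inclusive (weight >= threshold survives).  By default edges not
    touching a focal neuron pass through untouched; with
    ``only_focal=False`` every edge is thresholded.
    """
    if threshold < 1:
        raise ConfigError(f"threshold must be >= 1, got {threshold}")
    focal = set(focal_ids)
    out = []
    for e in edges:
        incident = e.pre_id in focal or e.post_id in focal
        if (incident or not only_focal) and e.weight < threshold:
            continue
        out.append(e)
    return out


def derive_scaled_threshold(
    ref_totals: list[int] | list[float],
    target_totals: list[int] | list[float],
    base_threshold: int,
) -> int:
    """Rescale a synapse threshold from a reference volume to a target volume.

    Returns ``round(base * sum(target) / sum(ref))`` with half rounded
    away from zero, floored at 1.  ``ref_totals``/``target_totals`` are
    per-focal-cell connection counts in the two volumes.
    """
    ref = float(sum(ref_totals))
    tgt = float(sum(target_totals))
    if ref <= 0:
        raise ValidationError("reference totals sum to zero; scaling ratio undefined")
    raw = base_threshold * tgt / ref
    rounded = math.floor(raw + 0.5)  # half away from zero (values here are positive)
    return max(1, rounded)


@dataclass
class ClassFractions:
    """Per-cell-class synapse totals and fractions for one focal neuron."""

    focal_id: str
    direction: str
    totals: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.totals.values())


def class_synapse_fractions(
    focal_id: str,
    edges: list[SynapseEdge],
    neurons: NeuronTable,
    direction: str = "upstream",
) -> ClassFractions:
    """Synapse fractions by partner cell class for one focal neuron.

    ``upstream`` counts edges onto the focal neuron (partners are
    presynaptic), ``downstream`` counts edges from it.  Orphan and
    undetermined fragments are excluded; fractions are each class's
    synapse sum over the included total.  Edges should already be
    thresholded.
    """
    if direction not in ("upstream", "downstream"):
        raise ConfigError(f"direction must be upstream|downstream, got {direction!r}")
    totals: dict[str, int] = {}
    for e in edges:
        if direction == "upstream" and e.post_id == focal_id:
            partner = e.pre_id
        elif direction == "downstream" and e.pre_id == focal_id:
            partner = e.post_id
        else:
            continue
        cls = neurons.class_of(partner)
        if cls in FRAGMENT_CLASSES:
            continue
        totals[cls.value] = totals.get(cls.value, 0) + e.weight
    grand = sum(totals.values())
    if grand == 0:
        warnings.warn(f"no partners above threshold for {focal_id} ({direction})",
                      stacklevel=2)
        return ClassFractions(focal_id, direction, {}, {})
    fractions = {k: v / grand for k, v in totals.items()}
    return ClassFractions(focal_id, direction, totals, fractions)


DN_SUM = "DN_sum"


def summarize_dn_inputs(
    edges: list[SynapseEdge],
    dn_types: dict[str, str],
    focal_groups: dict[str, str],
    min_fraction: float = 0.05,
) -> pd.DataFrame:
    """Type-to-type descending-neuron input fractions with a pooled remainder.

    For each focal group (e.g. a left/right-pooled cell type), the input
    fraction of a DN type is the summed weight from all DNs of that type
    onto all group members, over the group's total DN input.  A type whose
    fraction reaches ``min_fraction`` (inclusive) for ANY group is
    reported individually for every group; the rest are pooled into the
    ``DN_sum`` catch-all, so each group's reported fractions sum to 1.

    ``dn_types`` maps DN id -> type label ("untyped" allowed);
    ``focal_groups`` maps focal id -> group name.  Edges should already
    be thresholded.
    """
    rows = []
    for e in edges:
        if e.pre_id in dn_types and e.post_id in focal_groups:
            rows.append((dn_types[e.pre_id], focal_groups[e.post_id], e.weight))
    if not rows:
        warnings.warn("no DN input above threshold for any focal group", stacklevel=2)
        return pd.DataFrame(columns=sorted(set(focal_groups.values())))
    df = pd.DataFrame(rows, columns=["dn_type", "group", "weight"])
    mat = df.pivot_table(index="dn_type", columns="group", values="weight",
                         aggfunc="sum", fill_value=0)
    missing = sorted(set(focal_groups.values()) - set(mat.columns))
    for g in missing:
        warnings.warn(f"zero total DN input for group {g!r}; omitted", stacklevel=2)
    frac = mat / mat.sum(axis=0)
    keep = frac.index[(frac >= min_fraction).any(axis=1)]
    out = frac.loc[sorted(keep)]
    pooled = frac.drop(index=keep).sum(axis=0)
    if len(frac) > len(keep):
        out.loc[DN_SUM] = pooled
    out.columns.name = None
    out.index.name = "dn_type"
    return out


@dataclass
class SharedInputPartition:
    """Partition of thresholded partners by the focal subset they contact.

    ``groups`` maps each target-set signature (a sorted tuple of focal
    ids) to the partner ids carrying it; ``neuron_counts`` and
    ``synapse_counts`` are the per-signature sizes and summed weights the
    graph plots display.
    """

    focal_ids: tuple[str, ...]
    groups: dict[tuple[str, ...], list[str]]
    neuron_counts: dict[tuple[str, ...], int]
    synapse_counts: dict[tuple[str, ...], int]

    def partners_with_signature(self, signature: tuple[str, ...]) -> list[str]:
        return self.groups.get(tuple(sorted(signature)), [])

    @property
    def common_to_all(self) -> list[str]:
        return self.partners_with_signature(self.focal_ids)

    def to_graph_spec(self) -> dict:
        """JSON-ready node/edge spec for a shared-input graph plot."""
        nodes = [
            {"signature": list(sig), "n_neurons": self.neuron_counts[sig],
             "n_synapses": self.synapse_counts[sig]}
            for sig in sorted(self.groups)
        ]
        return {"focal_ids": list(self.focal_ids), "partner_groups": nodes}


def partition_shared_input(
    edges: list[SynapseEdge],
    focal_ids: list[str],
    neurons: NeuronTable | None = None,
    direction: str = "upstream",
) -> SharedInputPartition:
    """Group thresholded partners by which focal neurons they contact.

    Each partner is assigned the exact subset (signature) of focal
    neurons it connects to in the given direction; signatures partition
    the partner set.  Edges should already be thresholded, so surviving
    weight is the only criterion.
    """
    if not focal_ids:
        raise ConfigError("at least one focal neuron required")
    focal = list(dict.fromkeys(focal_ids))
    targets: dict[str, set[str]] = {}
    syn: dict[str, int] = {}
    for e in edges:
        if direction == "upstream" and e.post_id in set(focal) and e.pre_id not in focal:
            partner, f = e.pre_id, e.post_id
        elif direction == "downstream" and e.pre_id in set(focal) and e.post_id not in focal:
            partner, f = e.post_id, e.pre_id
        else:
            continue
        targets.setdefault(partner, set()).add(f)
        syn[partner] = syn.get(partner, 0) + e.weight
    groups: dict[tuple[str, ...], list[str]] = {}
    for partner, tset in targets.items():
        sig = tuple(sorted(tset))
        groups.setdefault(sig, []).append(partner)
    for members in groups.values():
        members.sort()
    neuron_counts = {sig: len(m) for sig, m in groups.items()}
    synapse_counts = {sig: sum(syn[p] for p in m) for sig, m in groups.items()}
    return SharedInputPartition(tuple(sorted(focal)), groups, neuron_counts, synapse_counts)


def synapse_locations_by_class(
    sites: list[SynapseSite],
    neurons: NeuronTable,
    focal_id: str | None = None,
) -> pd.DataFrame:
    """Tag each input synapse site with the presynaptic partner's cell class.

    Output columns: pre_id, x, y, z, cell_class — ready for xy / xz
    scatter projections of the synapse distribution over a focal neuron.
    Unresolvable partners are labeled ``undetermined``.
    """
    rows = []
    for s in sites:
        if focal_id is not None and s.post_id != focal_id:
            continue
        cls = neurons.class_of(s.pre_id)
        rows.append((s.pre_id, s.x, s.y, s.z, cls.value))
    return pd.DataFrame(rows, columns=["pre_id", "x", "y", "z", "cell_class"])
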