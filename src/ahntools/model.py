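"""Core domain types for connectome, morphology and imaging analyses.

Identifiers are opaque strings throughout, even when they look numeric:
connectome body ids routinely exceed 2**53 and survive CSV round-trips
only as text.  Directed synaptic edges carry integer weights; left/right
lives on the neuron annotation, never inside an id.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CellClass(str, enum.Enum):
    """Closed cell-class vocabulary used for synapse demographics.

    DN descending neuron, IN (VNC-restricted) interneuron, AN ascending
    central neuron, ASN ascending sensory neuron, SN sensory neuron,
    MN motor neuron, AEN ascending efferent neuron.  ``orphan`` and
    ``undetermined`` tag unannotated fragments; they are representable so
    raw totals can include them, but excluded from class demographics
    unless explicitly requested.
    """

    DN = "DN"
    IN = "IN"
    AN = "AN"
    ASN = "ASN"
    SN = "SN"
    MN = "MN"
    AEN = "AEN"
    orphan = "orphan"
    undetermined = "undetermined"


#: Classes counted in demographics; fragments are excluded.
VALID_CLASSES = frozenset(
    {CellClass.DN, CellClass.IN, CellClass.AN, CellClass.ASN,
     CellClass.SN, CellClass.MN, CellClass.AEN}
)

FRAGMENT_CLASSES = frozenset({CellClass.orphan, CellClass.undetermined})


class Side(str, enum.Enum):
    L = "L"
    R = "R"
    unknown = "unknown"


class SchemaError(ValueError):
    """A table is missing required columns or uses unknown vocabulary."""


class ValidationError(ValueError):
    """Row-level contract violation (duplicate ids, non-positive weights...)."""


class StructureError(ValueError):
    """A skeleton is not a rooted tree."""


class ConfigError(ValueError):
    """Invalid analysis or generator configuration."""


@dataclass(frozen=True)
class NeuronRecord:
    neuron_id: str
    cell_class: CellClass
    type_label: str | None = None
    side: Side = Side.unknown
    dataset: str = "synthetic"


@dataclass(frozen=True)
class SynapseEdge:
    """Directed connection pre -> post with an aggregate synapse count."""

    pre_id: str
    post_id: str
    weight: int

    def __post_init__(self) -> None:
        if not (isinstance(self.weight, (int, np.integer)) and self.weight >= 1):
            raise ValidationError(
                f"edge ({self.pre_id}->{self.post_id}) weight must be a "
                f"positive integer, got {self.weight!r}"
            )


class Polarity(str, enum.Enum):
    presynaptic = "presynaptic"
    postsynaptic = "postsynaptic"


@dataclass(frozen=True)
class SynapseSite:
    """A single synaptic contact with a 3D location (nanometres)."""

    pre_id: str
    post_id: str
    x: float
    y: float
    z: float
    polarity: Polarity

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(
                f"site ({self.pre_id}->{self.post_id}) has non-finite coordinates"
            )


class Units(str, enum.Enum):
    nm = "nm"
    um = "um"


@dataclass
class Skeleton:
    """Rooted tree morphology in SWC node form.

    ``nodes`` columns: node_id, parent_id (-1 marks the root), x, y, z,
    radius.  Coordinates are stored as read; ``units`` says what they
    mean instead of any silent conversion.
    """

    nodes: pd.DataFrame
    units: Units = Units.nm
    skeleton_id: str = ""

    REQUIRED = ("node_id", "parent_id", "x", "y", "z", "radius")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.nodes.columns]
        if missing:
            raise SchemaError(f"skeleton table missing columns: {missing}")
        self.nodes = self.nodes.reset_index(drop=True)
        self.units = Units(self.units)
        self.validate()

    # -- tree structure ------------------------------------------------
    def validate(self) -> None:
        ids = self.nodes["node_id"].to_numpy()
        if len(ids) == 0:
            raise StructureError("skeleton has no nodes")
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate node ids")
        parents = self.nodes["parent_id"].to_numpy()
        roots = ids[parents == -1]
        if len(roots) != 1:
            raise StructureError(f"skeleton must have exactly one root, found {len(roots)}")
        idset = set(ids)
        parent_of = dict(zip(ids, parents))
        for nid, pid in parent_of.items():
            if pid == -1:
                continue
            if pid == nid:
                raise StructureError(f"node {nid} is its own parent")
            if pid not in idset:
                raise StructureError(f"node {nid} references unknown parent {pid}")
        # walk each node to the root; revisiting a node on the same walk is a cycle
        ok: set = set()
        for nid in ids:
            seen = []
            cur = nid
            while cur != -1 and cur not in ok:
                if cur in seen:
                    raise StructureError(f"cycle through node {cur}")
                seen.append(cur)
                cur = parent_of[cur]
            ok.update(seen)

    @property
    def root(self) -> int:
        m = self.nodes["parent_id"] == -1
        return int(self.nodes.loc[m, "node_id"].iloc[0])

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(n): [] for n in self.nodes["node_id"]}
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out

    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "Skeleton":
        return Skeleton(self.nodes.copy(), units=self.units, skeleton_id=self.skeleton_id)


@dataclass(frozen=True)
class RoiCount:
    """Pre/postsynaptic site counts of one neuron in one neuropil ROI."""

    neuron_id: str
    roi: str
    pre_count: int
    post_count: int

    def __post_init__(self) -> None:
        if self.pre_count < 0 or self.post_count < 0:
            raise ValidationError(
                f"ROI counts must be non-negative ({self.neuron_id}, {self.roi})"
            )


@dataclass
class NeuronTable:
    """Collection of NeuronRecords with unique ids, indexable by id."""

    records: list[NeuronRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.neuron_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValidationError(f"duplicate neuron ids: {sorted(dupes)}")
        self._by_id = {r.neuron_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, neuron_id: str) -> bool:
        return neuron_id in self._by_id

    def get(self, neuron_id: str) -> NeuronRecord | None:
        return self._by_id.get(neuron_id)

    def class_of(self, neuron_id: str) -> CellClass:
        """Class lookup; unresolvable ids map to ``undetermined``."""
        rec = self._by_id.get(neuron_id)
        return rec.cell_class if rec is not None else CellClass.undetermined

    def ids_of_class(self, cell_class: CellClass) -> list[str]:
        return [r.neuron_id for r in self.records if r.cell_class == cell_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": [r.neuron_id for r in self.records],
                "cell_class": [r.cell_class.value for r in self.records],
                "type_label": [r.type_label if r.type_label is not None else "" for r in self.records],
                "side": [r.side.value for r in self.records],
                "dataset": [r.dataset for r in self.records],
            }
        )


def edges_to_frame(edges: list[SynapseEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pre_id": [e.pre_id for e in edges],
            "post_id": [e.post_id for e in edges],
            "weight": [int(e.weight) for e in edges],
        }
    )


def sites_to_frame(sites: list[SynapseSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pre_id": [s.pre_id for s in sites],
            "post_id": [s.post_id for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "z": [s.z for s in sites],
            "polarity": [s.polarity.value for s in sites],
        }
    )
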