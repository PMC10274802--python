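"""Seeded synthetic-data generators with planted, recoverable structure.

The generators emulate only the structure the analyses assume, not the
global statistics of any real EM volume:

* a class-labeled connectome in which a fraction of descending neurons
  (DNs) is planted as convergent common input onto two (or more) focal
  ascending-neuron pairs, plus a feedforward focal → interneuron → motor
  neuron chain per pair with segregated motor-neuron groups;
* branched tree skeletons with terminal twigs of exact requested cable
  lengths (fixtures for pruning and NBLAST tests);
* a cells × genes count matrix with planted marker-gene structure
  (an Hdc-like histamine marker plus two mutually exclusive Hox-like
  genes) over a sparse negative-binomial background;
* stimulus-locked exponential fluorescence transients over a stationary
  baseline.

Every generator is a pure function of its arguments including the seed;
each draws from its own RNG stream derived from the master seed by a
fixed label, so adding one generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CellClass,
    ConfigError,
    NeuronRecord,
    NeuronTable,
    Polarity,
    Side,
    Skeleton,
    SynapseEdge,
    SynapseSite,
    Units,
)

# fixed per-generator RNG stream labels
_STREAM = {"connectome": 101, "skeleton": 202, "expression": 303, "traces": 404}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM[stream]]))


# -- connectome -------------------------------------------------------------

#: class-specific coordinate boxes (nm) for synapse sites onto focal cells,
#: spatially separated so the synapse-location-by-class export shows structure
CLASS_BOXES: dict[CellClass, tuple[tuple[float, float], ...]] = {
    CellClass.DN: ((0, 20000), (0, 20000), (0, 10000)),
    CellClass.IN: ((30000, 50000), (0, 20000), (0, 10000)),
    CellClass.AN: ((60000, 80000), (0, 20000), (0, 10000)),
    CellClass.ASN: ((0, 20000), (30000, 50000), (0, 10000)),
    CellClass.SN: ((30000, 50000), (30000, 50000), (0, 10000)),
    CellClass.MN: ((60000, 80000), (30000, 50000), (0, 10000)),
}

#: motor-neuron group names by appendage, assigned to focal pairs in order
MN_GROUP_NAMES = ("MN_wing", "MN_leg", "MN_neck", "MN_haltere", "MN_abdominal")

FOCAL_PAIR_TYPES = ("MsAHN", "MtAHN", "AHN3", "AHN4", "AHN5")


@dataclass
class ConnectomeSpec:
    """Parameters of the planted synthetic connectome.

    Defaults give a population of ~270 background neurons around 2 focal
    pairs, with half of the DNs planted as convergent common input
    (mirroring the majority-DN shared input the demographic analyses
    expect) and one feedforward chain per pair onto its own motor-neuron
    group.
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {
        "DN": 60, "IN": 100, "AN": 20, "ASN": 20, "SN": 40, "MN": 30})
    n_focal_pairs: int = 2
    convergence_fraction: float = 0.5
    common_input_weights: tuple[int, int] = (10, 30)
    motif_weights: tuple[int, int] = (20, 40)
    chain_width: int = 4  # interneurons per planted chain
    background_density: float = 0.02
    weight_law: float = 0.35  # geometric p for background weights
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.convergence_fraction <= 1:
            raise ConfigError("convergence_fraction must lie in [0, 1]")
        if not 0 <= self.background_density <= 1:
            raise ConfigError("background_density must lie in [0, 1]")
        if not 0 < self.weight_law <= 1:
            raise ConfigError("weight_law (geometric p) must lie in (0, 1]")
        if any(v < 0 for v in self.n_per_class.values()):
            raise ConfigError("class counts must be non-negative")
        if self.n_focal_pairs < 1 or self.n_focal_pairs > len(FOCAL_PAIR_TYPES):
            raise ConfigError(f"n_focal_pairs must be 1..{len(FOCAL_PAIR_TYPES)}")
        need_in = self.chain_width * self.n_focal_pairs
        if self.n_per_class.get("IN", 0) < need_in:
            raise ConfigError(f"need >= {need_in} INs to host the planted chains")
        if self.n_per_class.get("MN", 0) < self.n_focal_pairs:
            raise ConfigError("need at least one MN per focal pair")
        if self.convergence_fraction > 0 and self.n_per_class.get("DN", 0) < 1:
            raise ConfigError("convergence_fraction > 0 requires DNs")


@dataclass
class GroundTruth:
    """Planted structure returned alongside generated data."""

    common_input_ids: list[str] = field(default_factory=list)
    motif_paths: list[tuple[str, str, str]] = field(default_factory=list)
    pair_mn_group: dict[str, str] = field(default_factory=dict)
    pair_intermediaries: dict[str, list[str]] = field(default_factory=dict)
    focal_ids: list[str] = field(default_factory=list)
    marker_cells: dict[str, list[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "common_input_ids": self.common_input_ids,
            "motif_paths": [list(p) for p in self.motif_paths],
            "pair_mn_group": self.pair_mn_group,
            "pair_intermediaries": self.pair_intermediaries,
            "focal_ids": self.focal_ids,
            "marker_cells": self.marker_cells,
        }


def gen_connectome(
    spec: ConnectomeSpec,
) -> tuple[NeuronTable, list[SynapseEdge], list[SynapseSite], GroundTruth]:
    """Generate a class-labeled connectome with planted convergent input
    and feedforward chains.

    Planted common-input DNs synapse on every focal cell with weights at
    or above the partner-inclusion threshold; each focal pair drives its
    own interneuron set which in turn drives a pair-specific motor-neuron
    group.  Background edges are sampled independently (density
    ``background_density``, geometric weights) and added on top; motor
    neurons emit no background output and sensory neurons receive none,
    matching their roles in the circuit.
    """
    spec.validate()
    rng = _rng(spec.seed, "connectome")

    records: list[NeuronRecord] = []
    # focal ascending pairs
    focal_ids: list[str] = []
    pair_types = FOCAL_PAIR_TYPES[: spec.n_focal_pairs]
    for ptype in pair_types:
        for side in (Side.L, Side.R):
            fid = f"{ptype}_{side.value}"
            records.append(NeuronRecord(fid, CellClass.AN, ptype, side))
            focal_ids.append(fid)

    by_class: dict[str, list[str]] = {}
    for cls_name, n in spec.n_per_class.items():
        cls = CellClass(cls_name)
        ids = [f"{cls_name}_{i:04d}" for i in range(n)]
        by_class[cls_name] = ids
        for i, nid in enumerate(ids):
            if cls_name == "DN":
                type_label = f"DNt{i // 3:02d}"  # ~3 cells per DN type
            elif cls_name == "IN":
                type_label = f"INt{i // 5:02d}"
            elif cls_name == "MN":
                type_label = MN_GROUP_NAMES[i % len(MN_GROUP_NAMES)]
            else:
                type_label = f"{cls_name}t{i // 5:02d}"
            side = Side.L if i % 2 == 0 else Side.R
            records.append(NeuronRecord(nid, cls, type_label, side))
    table = NeuronTable(records)

    weights: dict[tuple[str, str], int] = {}
    gt = GroundTruth(focal_ids=list(focal_ids))

    # planted convergent common input: each chosen DN onto every focal cell
    n_common = int(round(spec.convergence_fraction * len(by_class.get("DN", []))))
    common = sorted(rng.choice(by_class["DN"], size=n_common, replace=False)) \
        if n_common else []
    lo, hi = spec.common_input_weights
    for dn in common:
        for fid in focal_ids:
            weights[(dn, fid)] = int(rng.integers(lo, hi + 1))
    gt.common_input_ids = list(common)

    # planted feedforward chains with segregated MN groups
    mlo, mhi = spec.motif_weights
    in_pool = list(by_class["IN"])
    chain_ins = rng.choice(in_pool, size=spec.chain_width * spec.n_focal_pairs,
                           replace=False)
    type_of = {r.neuron_id: r.type_label for r in records}
    mn_by_group: dict[str, list[str]] = {}
    for nid in by_class["MN"]:
        mn_by_group.setdefault(type_of[nid], []).append(nid)
    for p, ptype in enumerate(pair_types):
        ins = sorted(chain_ins[p * spec.chain_width:(p + 1) * spec.chain_width])
        mn_group = MN_GROUP_NAMES[p]
        mns = mn_by_group[mn_group]
        gt.pair_mn_group[ptype] = mn_group
        gt.pair_intermediaries[ptype] = list(ins)
        pair_focals = [f"{ptype}_L", f"{ptype}_R"]
        for fid in pair_focals:
            for iid in ins:
                weights[(fid, iid)] = int(rng.integers(mlo, mhi + 1))
        for iid in ins:
            for mid in mns:
                weights[(iid, mid)] = int(rng.integers(mlo, mhi + 1))
                for fid in pair_focals:
                    gt.motif_paths.append((fid, iid, mid))

    # independent background: no MN output, no input onto sensory classes
    all_ids = [r.neuron_id for r in records]
    pre_ok = [i for i in all_ids if table.class_of(i) != CellClass.MN]
    post_ok = [i for i in all_ids
               if table.class_of(i) not in (CellClass.SN, CellClass.ASN)]
    mask = rng.random((len(pre_ok), len(post_ok))) < spec.background_density
    bg_w = rng.geometric(spec.weight_law, size=mask.shape)
    for ai, bi in zip(*np.nonzero(mask)):
        pre, post = pre_ok[ai], post_ok[bi]
        if pre == post:
            continue
        weights[(pre, post)] = weights.get((pre, post), 0) + int(bg_w[ai, bi])

    edges = [SynapseEdge(pre, post, w)
             for (pre, post), w in sorted(weights.items())]

    # per-synapse 3D sites for edges onto focal cells, inside class boxes
    sites: list[SynapseSite] = []
    focal_set = set(focal_ids)
    for e in edges:
        if e.post_id not in focal_set:
            continue
        box = CLASS_BOXES.get(table.class_of(e.pre_id))
        if box is None:
            continue
        for _ in range(e.weight):
            x, y, z = (rng.uniform(lo_, hi_) for lo_, hi_ in box)
            sites.append(SynapseSite(e.pre_id, e.post_id, x, y, z,
                                     Polarity.postsynaptic))
    return table, edges, sites, gt


# -- skeletons --------------------------------------------------------------

def gen_skeleton(
    seed: int,
    n_branches: int = 1,
    twig_lengths: tuple[float, ...] = (),
    trunk_length: float = 50.0,
    step: float = 1.0,
) -> Skeleton:
    """Generate a μm-unit tree: a straight trunk plus terminal twigs of
    exact cable length.

    ``n_branches`` counts linear segments (trunk + twigs), so it must
    equal ``1 + len(twig_lengths)``; ``n_branches=1`` yields an
    unbranched cable.  Each twig is attached at its own trunk node in
    the proximal half (keeping the trunk tip a long terminal segment)
    and runs straight in a random direction, subdivided so its path
    length is exactly the requested value.
    """
    if n_branches < 1:
        raise ConfigError("n_branches must be >= 1")
    twig_lengths = tuple(float(t) for t in twig_lengths)
    if any(t <= 0 for t in twig_lengths):
        raise ConfigError("twig lengths must be positive")
    if n_branches != 1 + len(twig_lengths):
        raise ConfigError(
            f"n_branches={n_branches} inconsistent with {len(twig_lengths)} twig(s); "
            "expected n_branches == 1 + len(twig_lengths)")
    rng = _rng(seed, "skeleton")
    n_trunk = max(2, int(round(trunk_length / step)) + 1)
    rows = []
    for i in range(n_trunk):
        rows.append((i + 1, i if i > 0 else -1, i * step, 0.0, 0.0, 0.1))
    next_id = n_trunk + 1
    attach_lo, attach_hi = 2, max(3, n_trunk // 2)
    attach_nodes = rng.choice(np.arange(attach_lo, attach_hi), size=len(twig_lengths),
                              replace=False) if twig_lengths else []
    for L, anode in zip(twig_lengths, attach_nodes):
        m = max(1, int(round(L / step)))
        seg = L / m
        d = rng.normal(size=3)
        d[0] = 0.4 * d[0]  # bias away from the trunk axis
        d /= np.linalg.norm(d)
        base = np.array(rows[int(anode) - 1][2:5], dtype=float)
        parent = int(anode)
        for j in range(1, m + 1):
            pt = base + d * seg * j
            rows.append((next_id, parent, pt[0], pt[1], pt[2], 0.1))
            parent = next_id
            next_id += 1
    df = pd.DataFrame(rows, columns=["node_id", "parent_id", "x", "y", "z", "radius"])
    return Skeleton(df, units=Units.um, skeleton_id=f"synth_{seed}")


# -- expression matrices ----------------------------------------------------

MARKER_GENES = ("Hdc", "Antp", "Ubx")


@dataclass(frozen=True)
class MarkerPlanEntry:
    """Raw marker counts to plant in one cell."""

    hdc: int
    antp: int
    ubx: int

    def expected_label(self, min_count: int = 2, dominance: float = 15.0) -> str:
        dom, minor = max(self.antp, self.ubx), min(self.antp, self.ubx)
        ratio = float("inf") if minor == 0 else dom / minor
        if (self.hdc >= min_count and self.antp != self.ubx
                and dom >= min_count and ratio >= dominance):
            return "MsAHN-like" if self.antp > self.ubx else "MtAHN-like"
        return "rejected"


def default_marker_plan(n_ms: int = 5, n_mt: int = 4,
                        n_decoys: int = 3) -> list[MarkerPlanEntry]:
    """Plan with clear mesothoracic-like and metathoracic-like candidates
    plus near-miss decoys that must be rejected."""
    plan = []
    for i in range(n_ms):
        plan.append(MarkerPlanEntry(hdc=5 + i, antp=16 + 3 * i, ubx=0 if i % 2 else 1))
    for i in range(n_mt):
        plan.append(MarkerPlanEntry(hdc=4 + i, antp=0, ubx=18 + 2 * i))
    decoys = [MarkerPlanEntry(hdc=1, antp=20, ubx=0),   # Hdc too low
              MarkerPlanEntry(hdc=8, antp=16, ubx=2),   # ratio 8 < 15
              MarkerPlanEntry(hdc=8, antp=1, ubx=1)]    # tied, sub-minimum Hox
    plan.extend(decoys[:n_decoys])
    return plan


def gen_expression(
    seed: int,
    n_cells: int = 2000,
    n_genes: int = 200,
    marker_plan: list[MarkerPlanEntry] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cells × genes raw count matrix with planted marker cells.

    Background counts follow a sparse negative binomial; background
    cells' marker-gene counts are 0/1 ambient contamination (marker
    genes are cell-type specific, so no unplanted cell can reach the
    2-count filter floor).  Planted cells sit at seeded random rows and
    carry the plan's marker counts verbatim.  Ground truth lists the
    planted cells expected to pass the filter, by label.
    """
    if n_genes < len(MARKER_GENES):
        raise ConfigError(f"n_genes must be >= {len(MARKER_GENES)}")
    if marker_plan is None:
        marker_plan = default_marker_plan()
    if len(marker_plan) > n_cells:
        raise ConfigError("more planted cells than cells")
    rng = _rng(seed, "expression")
    genes = list(MARKER_GENES) + [f"gene_{i:04d}" for i in range(n_genes - 3)]
    cells = [f"cell_{i:05d}" for i in range(n_cells)]
    counts = rng.negative_binomial(0.5, 0.4, size=(n_cells, n_genes))
    # ambient-level marker background: never reaches the 2-count floor
    counts[:, :3] = (rng.random((n_cells, 3)) < 0.03).astype(int)
    planted_rows = sorted(rng.choice(n_cells, size=len(marker_plan), replace=False))
    gt = GroundTruth()
    gt.marker_cells = {"MsAHN-like": [], "MtAHN-like": []}
    for row, entry in zip(planted_rows, marker_plan):
        counts[row, 0:3] = (entry.hdc, entry.antp, entry.ubx)
        label = entry.expected_label()
        if label != "rejected":
            gt.marker_cells[label].append(cells[row])
    matrix = pd.DataFrame(counts, index=cells, columns=genes)
    return matrix, gt


# -- fluorescence traces ----------------------------------------------------

def gen_traces(
    seed: int,
    n_frames: int = 600,
    rate_hz: float = 30.0,
    stim_frame: int = 300,
    amplitude: float = 50.0,
    tau: float = 2.0,
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    background_level: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Generate a stimulus-locked exponential fluorescence transient.

    The focal trace is ``baseline + background_level`` before the
    stimulus and adds ``amplitude * exp(-(t - t_stim)/tau)`` after; the
    background trace is a constant offset.  Independent Gaussian noise
    of ``noise_sd`` is added to both.  After frame-wise background
    subtraction and baseline normalization the noiseless peak ΔF/F is
    exactly amplitude / baseline.

    Returns (focal trace, background trace, stimulus time in seconds).
    """
    if rate_hz <= 0:
        raise ConfigError("frame rate must be positive")
    if not 0 < stim_frame < n_frames:
        raise ConfigError("stim_frame must lie strictly inside the recording")
    rng = _rng(seed, "traces")
    t = np.arange(n_frames) / rate_hz
    t_stim = stim_frame / rate_hz
    transient = np.where(t >= t_stim,
                         amplitude * np.exp(-(t - t_stim) / tau), 0.0)
    focal = baseline + background_level + transient
    background = np.full(n_frames, background_level)
    if noise_sd > 0:
        focal = focal + rng.normal(0, noise_sd, n_frames)
        background = background + rng.normal(0, noise_sd, n_frames)
    return focal, background, t_stim
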