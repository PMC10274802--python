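"""Readers and writers for the tabular and SWC formats the analyses consume.

All downstream modules consume the parsed domain types; nothing re-parses
files.  CSV/TSV delimiters are auto-detected; writers emit a
``# schema_version`` header comment and canonicalize row order by id so a
write/read round-trip is bit-exact.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import pandas as pd

from .model import (
    CellClass,
    NeuronRecord,
    NeuronTable,
    Polarity,
    RoiCount,
    SchemaError,
    Side,
    Skeleton,
    SynapseEdge,
    SynapseSite,
    Units,
    ValidationError,
    edges_to_frame,
    sites_to_frame,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                try:
                    return csv.Sniffer().sniff(line, delimiters=",\t;").delimiter
                except csv.Error:
                    return ","
    return ","


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION} kind: {kind}\n")
        df.to_csv(fh, index=False)


# -- neuron annotation tables -----------------------------------------------

def read_neuron_table(path: str | Path) -> NeuronTable:
    """Parse a neuron annotation table (neuron_id, cell_class, type_label, side).

    Unknown class strings are rejected with the offending rows listed;
    duplicate neuron ids raise a validation error.
    """
    df = _read_table(path, ("neuron_id", "cell_class", "type_label", "side"))
    valid = {c.value for c in CellClass}
    bad = df.loc[~df["cell_class"].isin(valid)]
    if len(bad):
        rows = ", ".join(f"row {i}: {c!r}" for i, c in
                         zip(bad.index + 2, bad["cell_class"]))
        raise SchemaError(f"unknown cell_class values ({rows})")
    records = [
        NeuronRecord(
            neuron_id=row.neuron_id,
            cell_class=CellClass(row.cell_class),
            type_label=row.type_label or None,
            side=Side(row.side) if row.side in {"L", "R"} else Side.unknown,
            dataset=getattr(row, "dataset", "") or "synthetic",
        )
        for row in df.itertuples()
    ]
    return NeuronTable(records)


def write_neuron_table(table: NeuronTable, path: str | Path) -> None:
    df = table.to_frame().sort_values("neuron_id", kind="stable").reset_index(drop=True)
    _write_table(df, path, "neurons")


# -- synaptic edge tables ---------------------------------------------------

def read_edge_table(path: str | Path) -> list[SynapseEdge]:
    """Parse a directed edge table (pre_id, post_id, weight).

    Duplicate (pre, post) rows are summed with a logged warning; weights
    must coerce to positive integers.
    """
    df = _read_table(path, ("pre_id", "post_id", "weight"))
    if len(df) == 0:
        return []
    try:
        weights = pd.to_numeric(df["weight"])
    except ValueError as exc:
        raise ValidationError(f"non-numeric weight: {exc}") from exc
    if (weights != weights.astype(int)).any():
        raise ValidationError("edge weights must be integers")
    df = df.assign(weight=weights.astype(int))
    if (df["weight"] <= 0).any():
        bad = df.loc[df["weight"] <= 0]
        raise ValidationError(
            f"non-positive edge weights at rows {list(bad.index + 2)}"
        )
    n_before = len(df)
    merged = df.groupby(["pre_id", "post_id"], as_index=False, sort=False)["weight"].sum()
    if len(merged) != n_before:
        msg = f"{n_before - len(merged)} duplicate (pre,post) rows summed"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return [SynapseEdge(r.pre_id, r.post_id, int(r.weight)) for r in merged.itertuples()]


def write_edge_table(edges: list[SynapseEdge], path: str | Path) -> None:
    df = edges_to_frame(edges).sort_values(
        ["pre_id", "post_id"], kind="stable").reset_index(drop=True)
    _write_table(df, path, "edges")


# -- synapse site tables ----------------------------------------------------

def read_site_table(path: str | Path) -> list[SynapseSite]:
    df = _read_table(path, ("pre_id", "post_id", "x", "y", "z", "polarity"))
    return [
        SynapseSite(r.pre_id, r.post_id, float(r.x), float(r.y), float(r.z),
                    Polarity(r.polarity))
        for r in df.itertuples()
    ]


def write_site_table(sites: list[SynapseSite], path: str | Path) -> None:
    df = sites_to_frame(sites).sort_values(
        ["pre_id", "post_id", "x", "y", "z"], kind="stable").reset_index(drop=True)
    _write_table(df, path, "sites")


# -- ROI count tables -------------------------------------------------------

def read_roi_table(path: str | Path) -> list[RoiCount]:
    df = _read_table(path, ("neuron_id", "roi", "pre_count", "post_count"))
    return [
        RoiCount(r.neuron_id, r.roi, int(r.pre_count), int(r.post_count))
        for r in df.itertuples()
    ]


def write_roi_table(rois: list[RoiCount], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in rois],
            "roi": [r.roi for r in rois],
            "pre_count": [r.pre_count for r in rois],
            "post_count": [r.post_count for r in rois],
        }
    ).sort_values(["neuron_id", "roi"], kind="stable").reset_index(drop=True)
    _write_table(df, path, "roi_counts")


# -- SWC skeletons ----------------------------------------------------------

def read_swc(path: str | Path, units: Units | str = Units.nm,
             skeleton_id: str | None = None) -> Skeleton:
    """Parse a 7-column SWC file into a validated Skeleton.

    SWC columns: id, structure type, x, y, z, radius, parent (-1 = root).
    ``#`` comment lines are permitted.  Units come from the caller
    (default nm) because SWC carries no unit metadata.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SchemaError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
            nid, _stype, x, y, z, radius, parent = parts
            rows.append((int(nid), int(parent), float(x), float(y), float(z), float(radius)))
    df = pd.DataFrame(rows, columns=["node_id", "parent_id", "x", "y", "z", "radius"])
    return Skeleton(df, units=Units(units),
                    skeleton_id=skeleton_id if skeleton_id is not None else path.stem)


def write_swc(skeleton: Skeleton, path: str | Path) -> None:
    path = Path(path)
    df = skeleton.nodes.sort_values("node_id", kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION} kind: swc units: {skeleton.units.value}\n")
        fh.write("# id type x y z radius parent\n")
        for r in df.itertuples():
            fh.write(f"{int(r.node_id)} 0 {r.x:.6g} {r.y:.6g} {r.z:.6g} "
                     f"{r.radius:.6g} {int(r.parent_id)}\n")
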