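"""Accessors for the small reference tables packaged with the library.

Two published summary tables ship as CSV fixtures: the per-cell AHN
connectivity summary across the three EM volumes (used to rescale
synapse thresholds between volumes), and the candidate-AHN cells from
the adult VNC single-cell atlas with their normalized marker expression.
A synthetic NBLAST scoring-matrix fixture is included for tests and
demos; trained fly-neuron matrices can be loaded from the same CSV
layout via :func:`ahntools.morphology.read_scoring_matrix`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .demographics import derive_scaled_threshold
from .morphology import ScoringMatrix, read_scoring_matrix


def _path(name: str):
    return resources.files("ahntools").joinpath("data", name)


def connectivity_summary() -> pd.DataFrame:
    """Published per-cell AHN synaptic-site and connection counts
    (FANC, MANC and FAFB volumes)."""
    with resources.as_file(_path("ahn_connectivity_summary.csv")) as p:
        return pd.read_csv(p)


def candidate_cells() -> pd.DataFrame:
    """Published candidate-AHN cells from the adult VNC single-cell atlas
    with CPM-log2-normalized Hdc/Antp/Ubx expression."""
    with resources.as_file(_path("ahn_candidate_cells.csv")) as p:
        return pd.read_csv(p)


def synthetic_scoring_matrix() -> ScoringMatrix:
    """Synthetic smooth log-odds scoring matrix (not a trained artifact)."""
    with resources.as_file(_path("nblast_scores_synthetic.csv")) as p:
        return read_scoring_matrix(p)


def manc_thresholds(base_threshold: int = 3) -> tuple[int, int]:
    """Derive the (upstream, downstream) MANC partner-inclusion thresholds
    from the packaged connectivity summary.

    The upstream ratio compares connections from valid neurons in the two
    nerve-cord volumes; the downstream ratio uses FANC valid + undetermined
    connections (reconstruction in MANC pre-filtered downstream bodies, so
    undetermined fragments belong in the reference total).
    """
    df = connectivity_summary()
    fanc = df[df.dataset == "FANC"]
    manc = df[df.dataset == "MANC"]
    up = derive_scaled_threshold(
        fanc["upstream_valid_connections"].astype(float).tolist(),
        manc["upstream_valid_connections"].astype(float).tolist(),
        base_threshold,
    )
    down = derive_scaled_threshold(
        (fanc["downstream_valid"] + fanc["downstream_undetermined"]).astype(float).tolist(),
        manc["downstream_connections"].astype(float).tolist(),
        base_threshold,
    )
    return up, down
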