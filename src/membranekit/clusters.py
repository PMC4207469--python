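"""Density-based lipid nano-cluster detection and protein connectivity.

Lipid nano-domains are found with DBSCAN on the lateral head-centroid
positions (periodic distances), using a 15 A neighbour cutoff and a
minimum of 3 elements; cluster sizes are reported in the standard bins
1-3 (non-clustered), 4-20 (small), 21-40 (medium) and >40 (large).
Proteins are clustered by single-linkage connectivity: two proteins are
linked when any inter-protein bead pair is within 8 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import MembraneFrame
from .geometry import wrap_coords
from .species import PROTEIN_SPECIES

__all__ = [
    "ClusterParameters",
    "ClusterRecord",
    "dbscan_periodic",
    "size_bin_fractions",
    "cluster_timeseries",
    "protein_clusters",
    "SIZE_BINS",
]

SIZE_BINS: tuple[tuple[int, int | None], ...] = ((1, 3), (4, 20), (21, 40), (41, None))
BIN_LABELS = ("non_clustered", "small", "medium", "large")


@dataclass
class ClusterParameters:
    eps: float = 15.0  # A neighbour cutoff
    min_elements: int = 3  # minimum neighbourhood size, the point itself included
    size_bins: tuple[tuple[int, int | None], ...] = SIZE_BINS
    protein_cutoff: float = 8.0  # A single-linkage protein connectivity

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        lo = 1
        for a, b in self.size_bins:
            if a != lo:
                raise ValueError("size bins must be contiguous starting at 1")
            lo = (b + 1) if b is not None else None
        if lo is not None:
            raise ValueError("last size bin must be open-ended")


@dataclass
class ClusterRecord:
    time: float
    labels: np.ndarray  # per-lipid cluster label; noise points get singleton labels
    sizes: np.ndarray  # size of each cluster label present
    bin_fractions: np.ndarray  # lipid fraction per size bin


def dbscan_periodic(points: np.ndarray, box_xy, eps: float, min_elements: int) -> np.ndarray:
    """DBSCAN with periodic lateral distances.

    A point is core when its eps-neighbourhood (itself included) holds at
    least ``min_elements`` points; clusters are the connected components
    of the core points, border points join the cluster of their
    lowest-index core neighbour, and every noise point receives its own
    singleton label.  The deterministic border rule makes runs
    reproducible under a fixed point order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    box_xy = np.asarray(box_xy, dtype=float)[:2]
    tree = cKDTree(np.mod(points[:, :2], box_xy), boxsize=box_xy)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    deg = np.bincount(pairs.ravel(), minlength=n) if len(pairs) else np.zeros(n, dtype=int)
    core = (deg + 1) >= min_elements

    labels = np.full(n, -1, dtype=int)
    n_clusters = 0
    if core.any():
        cc_pairs = pairs[core[pairs[:, 0]] & core[pairs[:, 1]]] if len(pairs) else pairs
        core_idx = np.flatnonzero(core)
        remap = -np.ones(n, dtype=int)
        remap[core_idx] = np.arange(len(core_idx))
        if len(cc_pairs):
            g = coo_matrix(
                (np.ones(len(cc_pairs)), (remap[cc_pairs[:, 0]], remap[cc_pairs[:, 1]])),
                shape=(len(core_idx), len(core_idx)),
            )
            n_clusters, comp = connected_components(g, directed=False)
        else:
            n_clusters, comp = len(core_idx), np.arange(len(core_idx))
        labels[core_idx] = comp
        # border points: lowest-index core neighbour decides the cluster
        if len(pairs):
            border_edges = []
            for a, b in pairs:
                if core[a] and not core[b]:
                    border_edges.append((b, a))
                elif core[b] and not core[a]:
                    border_edges.append((a, b))
            best: dict[int, int] = {}
            for pt, c in border_edges:
                if pt not in best or c < best[pt]:
                    best[pt] = c
            for pt, c in best.items():
                labels[pt] = labels[c]
    # noise points get singleton labels after the cluster labels
    noise = np.flatnonzero(labels < 0)
    labels[noise] = n_clusters + np.arange(len(noise))
    return labels


def size_bin_fractions(labels: np.ndarray, bins=SIZE_BINS) -> np.ndarray:
    """Fraction of points per cluster-size bin (fractions sum to 1)."""
    if len(labels) == 0:
        return np.zeros(len(bins))
    sizes = np.bincount(labels)
    per_point_size = sizes[labels]
    out = np.zeros(len(bins))
    for k, (lo, hi) in enumerate(bins):
        m = per_point_size >= lo
        if hi is not None:
            m &= per_point_size <= hi
        out[k] = m.sum() / len(labels)
    return out


def cluster_timeseries(
    traj_or_frames,
    species: str,
    leaflet: str = "outer",
    params: ClusterParameters | None = None,
    tail_window: float = 0.25,
) -> tuple[list[ClusterRecord], pd.DataFrame, dict]:
    """Per-frame DBSCAN cluster records and binned size time series.

    The summary reports mean bin fractions over the final
    ``tail_window`` fraction of the trajectory (a convergence estimate).
    """
    params = params or ClusterParameters()
    frames = traj_or_frames if isinstance(traj_or_frames, (list, tuple)) else list(traj_or_frames)
    records: list[ClusterRecord] = []
    rows = []
    for f in frames:
        sel = f.select_molecules(species=species, leaflet=leaflet, lipids_only=True)
        if len(sel) == 0:
            raise ValueError(f"no {species} lipids in {leaflet} leaflet")
        pts = f.head_centroids(sel)[:, :2]
        labels = dbscan_periodic(pts, f.box[:2], params.eps, params.min_elements)
        sizes = np.bincount(labels)
        fractions = size_bin_fractions(labels, params.size_bins)
        records.append(ClusterRecord(time=f.time, labels=labels, sizes=sizes, bin_fractions=fractions))
        rows.append(
            {
                "time_ns": f.time,
                **{lab: fr for lab, fr in zip(BIN_LABELS, fractions)},
                "n_clusters": int((sizes >= params.size_bins[1][0]).sum()),
                "largest": int(sizes.max()),
            }
        )
    df = pd.DataFrame(rows)
    n_tail = max(1, int(round(tail_window * len(records))))
    tail = df.iloc[-n_tail:]
    summary = {lab: float(tail[lab].mean()) for lab in BIN_LABELS}
    summary["n_frames"] = len(records)
    return records, df, summary


def protein_clusters(traj_or_frames, params: ClusterParameters | None = None) -> pd.DataFrame:
    """Single-linkage protein clusters per frame (8 A bead-pair linkage)."""
    params = params or ClusterParameters()
    frames = traj_or_frames if isinstance(traj_or_frames, (list, tuple)) else list(traj_or_frames)
    rows = []
    for f in frames:
        sel = f.select_molecules(species=PROTEIN_SPECIES)
        if len(sel) == 0:
            raise ValueError("no proteins in frame")
        pos, owner = f.bead_positions(sel, "head")
        tree = cKDTree(wrap_coords(pos, f.box), boxsize=f.box)
        pairs = tree.query_pairs(params.protein_cutoff, output_type="ndarray")
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in sel)
        if len(pairs):
            mp = owner[pairs]
            mp = mp[mp[:, 0] != mp[:, 1]]
            g.add_edges_from((int(a), int(b)) for a, b in mp)
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        rows.append(
            {
                "time_ns": f.time,
                "n_clusters": len(sizes),
                "largest": sizes[0],
                "sizes": sizes,
            }
        )
    return pd.DataFrame(rows)
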