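"""Grid-based curvature-composition cross-correlation and related maps.

The membrane is split into an 8x8 lateral grid (default).  For a species
L, ``R_L,z`` is the Pearson correlation across grid boxes between the
per-box lipid count ``L_n`` and the per-box surface height ``z_n`` --
the mean z of the head/tail interface beads of all lipids in the box
*excluding* the species being correlated.  With the outer leaflet viewed
from the extracellular side, enrichment in concave (low-z) regions gives
a negative R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MembraneFrame

__all__ = [
    "GridField",
    "CurvatureCorrelation",
    "grid_decompose",
    "curvature_composition_correlation",
    "interleaflet_correlation",
    "local_thickness",
    "pearson_correlation",
]

logger = logging.getLogger(__name__)


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from explicit sums; 0 when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    vx = np.sum(dx * dx)
    vy = np.sum(dy * dy)
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(np.sum(dx * dy) / np.sqrt(vx * vy))


@dataclass
class GridField:
    """Per-box species counts and interface-z sums for one leaflet frame."""

    dims: tuple[int, int]
    box: np.ndarray
    leaflet: str
    species: list[str]
    counts: np.ndarray  # (k, n_boxes) integer lipid counts
    z_sums: np.ndarray  # (k, n_boxes) summed interface-bead z per species
    time: float = 0.0

    @property
    def n_boxes(self) -> int:
        return self.dims[0] * self.dims[1]

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts[self.species.index(name)]

    def surface_z(self, exclude: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(z_n, valid mask); z_n excludes the species being correlated."""
        tot_n = self.counts.sum(axis=0).astype(float)
        tot_z = self.z_sums.sum(axis=0)
        if exclude is not None and exclude in self.species:
            i = self.species.index(exclude)
            tot_n = tot_n - self.counts[i]
            tot_z = tot_z - self.z_sums[i]
        valid = tot_n > 0
        z = np.full(self.n_boxes, np.nan)
        z[valid] = tot_z[valid] / tot_n[valid]
        return z, valid


@dataclass
class CurvatureCorrelation:
    species: str
    leaflet: str
    mean: float
    sd: float
    per_frame: np.ndarray
    n_frames: int
    zero_variance_frames: int


def _box_indices(xy: np.ndarray, box, dims: tuple[int, int]) -> np.ndarray:
    """Half-open periodic box assignment: edge points go to the higher box."""
    nx, ny = dims
    ix = np.floor(np.mod(xy[:, 0], box[0]) / box[0] * nx).astype(int) % nx
    iy = np.floor(np.mod(xy[:, 1], box[1]) / box[1] * ny).astype(int) % ny
    return ix * ny + iy


def grid_decompose(
    frame: MembraneFrame,
    leaflet: str = "outer",
    dims: tuple[int, int] = (8, 8),
) -> GridField:
    """Bin one leaflet's lipids into a lateral grid.

    Lipids are binned by head-centroid lateral position; each box also
    accumulates the z of the per-lipid interface bead (first tail bead),
    from which the surface height excluding any one species follows.
    """
    if dims[0] < 2 or dims[1] < 2:
        raise ValueError("grid must be at least 2x2")
    sel = frame.select_molecules(leaflet=leaflet, lipids_only=True)
    if len(sel) == 0:
        raise ValueError(f"no lipids in leaflet {leaflet!r}")
    species = sorted(set(frame.species[sel].astype(str)))
    n_boxes = dims[0] * dims[1]
    counts = np.zeros((len(species), n_boxes), dtype=int)
    z_sums = np.zeros((len(species), n_boxes))

    centroids = frame.head_centroids(sel)
    boxes = _box_indices(centroids[:, :2], frame.box, dims)
    iface_pos, iface_owner = frame.bead_positions(sel, "interface")
    iface_z = np.full(frame.n_molecules, np.nan)
    iface_z[iface_owner] = iface_pos[:, 2]
    sp_arr = frame.species[sel].astype(str)
    for si, s in enumerate(species):
        m = sp_arr == s
        counts[si] = np.bincount(boxes[m], minlength=n_boxes)
        z_sums[si] = np.bincount(boxes[m], weights=iface_z[sel[m]], minlength=n_boxes)
    if counts.sum() == 0:
        raise ValueError("all grid boxes empty")
    return GridField(
        dims=dims, box=frame.box, leaflet=leaflet, species=species, counts=counts, z_sums=z_sums, time=frame.time
    )


def curvature_composition_correlation(
    traj_or_frames,
    leaflet: str,
    species: str,
    dims: tuple[int, int] = (8, 8),
) -> CurvatureCorrelation:
    """Mean +/- SD over frames of the per-frame R_L,z for one species.

    Per frame, R is the Pearson correlation over non-empty grid boxes
    between the species counts and the surface height computed from all
    other species; frames in which either side has zero variance
    contribute R = 0 and are counted in ``zero_variance_frames``.
    """
    frames = traj_or_frames if isinstance(traj_or_frames, (list, tuple)) else list(traj_or_frames)
    values = []
    n_zero = 0
    for f in frames:
        gf = grid_decompose(f, leaflet, dims)
        if species not in gf.species:
            raise ValueError(f"species {species} absent from {leaflet} leaflet")
        z, valid = gf.surface_z(exclude=species)
        if valid.sum() < 2:
            raise ValueError("fewer than two non-empty grid boxes")
        L = gf.species_counts(species)[valid].astype(float)
        r = pearson_correlation(L, z[valid])
        if np.std(z[valid]) == 0 or np.std(L) == 0:
            n_zero += 1
            logger.debug("zero-variance frame at t=%.3f ns contributes R=0", f.time)
        values.append(r)
    values = np.array(values)
    return CurvatureCorrelation(
        species=species,
        leaflet=leaflet,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        per_frame=values,
        n_frames=len(values),
        zero_variance_frames=n_zero,
    )


def interleaflet_correlation(traj_or_frames, dims: tuple[int, int] = (8, 8)) -> pd.DataFrame:
    """Correlation between outer and inner species counts per grid box.

    For each (outer species A, inner species B) pair the per-box counts
    are pooled over frames and correlated across the laterally matched
    boxes; negative values mean the species avoid the same lateral
    regions of the membrane.
    """
    frames = traj_or_frames if isinstance(traj_or_frames, (list, tuple)) else list(traj_or_frames)
    outer_counts: dict[str, list[np.ndarray]] = {}
    inner_counts: dict[str, list[np.ndarray]] = {}
    for f in frames:
        for leaflet, store in (("outer", outer_counts), ("inner", inner_counts)):
            gf = grid_decompose(f, leaflet, dims)
            for s in gf.species:
                store.setdefault(s, []).append(gf.species_counts(s).astype(float))
    if not outer_counts or not inner_counts:
        raise ValueError("both leaflets must be populated")
    out = pd.DataFrame(index=sorted(outer_counts), columns=sorted(inner_counts), dtype=float)
    for a, av in outer_counts.items():
        for b, bv in inner_counts.items():
            out.loc[a, b] = pearson_correlation(np.concatenate(av), np.concatenate(bv))
    return out


def local_thickness(traj_or_frames, dims: tuple[int, int] = (8, 8)) -> dict:
    """Per-box head-tail interface separation and its height correlation.

    Thickness per box is the outer-minus-inner interface z separation;
    its correlation with the local mid-height should vanish for
    congruently displaced (constant-thickness) membranes.
    """
    frames = traj_or_frames if isinstance(traj_or_frames, (list, tuple)) else list(traj_or_frames)
    thickness, height = [], []
    n_boxes = dims[0] * dims[1]
    mean_map = np.zeros(n_boxes)
    map_n = np.zeros(n_boxes)
    for f in frames:
        zo, vo = grid_decompose(f, "outer", dims).surface_z()
        zi, vi = grid_decompose(f, "inner", dims).surface_z()
        valid = vo & vi
        th = zo[valid] - zi[valid]
        thickness.append(th)
        height.append(0.5 * (zo[valid] + zi[valid]))
        mean_map[valid] += th
        map_n[valid] += 1
    thickness = np.concatenate(thickness)
    height = np.concatenate(height)
    with np.errstate(invalid="ignore"):
        per_box_mean = np.where(map_n > 0, mean_map / np.maximum(map_n, 1), np.nan)
    return {
        "per_box_mean_thickness_A": per_box_mean.reshape(dims),
        "thickness_mean_A": float(thickness.mean()),
        "thickness_sd_A": float(thickness.std()),
        "height_correlation": pearson_correlation(thickness, height),
        "n_frames": len(frames),
    }
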