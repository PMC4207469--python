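"""Lipid-lipid fractional interactions, lateral RDFs, protein contacts.

Two lipids are in contact when the minimum-image distance between any
pair of their linker beads (glycerol-ester or amide moieties) is below
the cutoff (default 11 A); multiple qualifying bead pairs still count as
one contact.  Fractional interactions are contact counts corrected for
species abundance, so a fully mixed system of k species gives 1/k in
every matrix entry regardless of the composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import MembraneFrame, Trajectory
from .geometry import min_image_displacement, wrap_coords
from .species import PROTEIN_SPECIES

__all__ = [
    "ContactParameters",
    "FractionalInteractionMatrix",
    "lipid_pair_contacts",
    "fractional_interactions",
    "lateral_rdf",
    "residue_lipid_contacts",
]

logger = logging.getLogger(__name__)


@dataclass
class ContactParameters:
    lipid_contact_cutoff: float = 11.0  # A, strict less-than
    protein_contact_cutoff: float = 6.0  # A
    window: tuple[float, float] | None = None  # (start ns, end ns)
    stride: float | None = None  # ns

    def __post_init__(self) -> None:
        if self.lipid_contact_cutoff <= 0 or self.protein_contact_cutoff <= 0:
            raise ValueError("contact cutoffs must be positive")


@dataclass
class FractionalInteractionMatrix:
    """Row-stochastic abundance-corrected contact fractions per leaflet."""

    leaflet: str
    species: list[str]
    fractions: np.ndarray  # (k, k), rows sum to 1
    raw_pairs: np.ndarray  # (k, k) summed unordered pair counts (symmetric)
    n_frames: int
    parameters: ContactParameters

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.species, columns=self.species)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.fractions[self.species.index(a), self.species.index(b)])


def _frames_of(traj_or_frames, params: ContactParameters | None) -> list[MembraneFrame]:
    if isinstance(traj_or_frames, Trajectory):
        if params is not None and (params.window or params.stride):
            start, end = params.window if params.window else (None, None)
            return traj_or_frames.window(start, end, params.stride)
        return list(traj_or_frames)
    if isinstance(traj_or_frames, MembraneFrame):
        return [traj_or_frames]
    return list(traj_or_frames)


def _molecule_contact_pairs(frame: MembraneFrame, mol_sel: np.ndarray, cutoff: float) -> np.ndarray:
    """Unordered molecule index pairs with any linker-linker distance < cutoff."""
    pos, owner = frame.bead_positions(mol_sel, "linker")
    if len(pos) < 2:
        return np.zeros((0, 2), dtype=int)
    tree = cKDTree(wrap_coords(pos, frame.box), boxsize=frame.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=int)
    # enforce the strict "less than" of the contact rule
    d = np.linalg.norm(min_image_displacement(pos[pairs[:, 1]] - pos[pairs[:, 0]], frame.box), axis=-1)
    pairs = pairs[d < cutoff]
    mp = owner[pairs]
    mp = mp[mp[:, 0] != mp[:, 1]]
    mp = np.sort(mp, axis=1)
    return np.unique(mp, axis=0)


def lipid_pair_contacts(
    frame: MembraneFrame,
    leaflet: str = "outer",
    params: ContactParameters | None = None,
    exclude: Sequence[str] = ("CHOL",),
) -> dict[tuple[str, str], int]:
    """Distinct in-contact lipid pairs per (sorted) species pair.

    Cholesterol is excluded by default because it cannot be assigned to
    a single leaflet over time.
    """
    params = params or ContactParameters()
    sel = frame.select_molecules(leaflet=leaflet, exclude_species=exclude, lipids_only=True)
    for sp_name in set(frame.species[sel].astype(str)):
        from .species import get_species

        if not get_species(sp_name).linker_beads:
            raise ValueError(f"{sp_name} has no linker beads defined")
    pairs = _molecule_contact_pairs(frame, sel, params.lipid_contact_cutoff)
    out: dict[tuple[str, str], int] = {}
    sp = frame.species.astype(str)
    for i, j in pairs:
        key = tuple(sorted((sp[i], sp[j])))
        out[key] = out.get(key, 0) + 1
    return out


def fractional_interactions(
    traj_or_frames,
    leaflet: str = "outer",
    params: ContactParameters | None = None,
    exclude: Sequence[str] = ("CHOL",),
) -> FractionalInteractionMatrix:
    """Abundance-corrected fractional interaction matrix.

    Pair counts are summed over frames, converted to per-ordered-pair
    contact rates ``r(A->B) = C(A,B) / sum_t N_A N_B`` (with ``N_A-1``
    replacing ``N_B`` on the diagonal), then row-normalised.  Under
    uniform random mixing of k species every entry is 1/k regardless of
    the composition, reproducing the 0.5 / 0.25 two- and four-species
    baselines of a fully mixed bilayer.
    """
    params = params or ContactParameters()
    frames = _frames_of(traj_or_frames, params)
    if not frames:
        raise ValueError("no frames in the requested window")

    all_species: set[str] = set()
    for f in frames:
        sel = f.select_molecules(leaflet=leaflet, exclude_species=exclude, lipids_only=True)
        all_species |= set(f.species[sel].astype(str))
    species = sorted(all_species)
    k = len(species)
    idx = {s: i for i, s in enumerate(species)}
    pair_counts = np.zeros((k, k))
    denom = np.zeros((k, k))
    absent: set[str] = set()
    for f in frames:
        sel = f.select_molecules(leaflet=leaflet, exclude_species=exclude, lipids_only=True)
        sp = f.species[sel].astype(str)
        n = np.zeros(k)
        for s, c in zip(*np.unique(sp, return_counts=True)):
            n[idx[s]] = c
        absent |= {s for s in species if n[idx[s]] == 0}
        denom += np.outer(n, n) - np.diag(n)  # N_A*N_B off-diag, N_A*(N_A-1) diag
        for (a, b), c in lipid_pair_contacts(f, leaflet, params, exclude).items():
            ia, ib = idx[a], idx[b]
            if ia == ib:
                pair_counts[ia, ia] += 2 * c  # ordered count: both directions
            else:
                pair_counts[ia, ib] += c
                pair_counts[ib, ia] += c
    if absent:
        logger.warning("species absent from %s leaflet in some frames: %s", leaflet, sorted(absent))
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(denom > 0, pair_counts / np.maximum(denom, 1e-300), 0.0)
        row_sums = rates.sum(axis=1, keepdims=True)
        fractions = np.where(row_sums > 0, rates / np.maximum(row_sums, 1e-300), 0.0)
    return FractionalInteractionMatrix(
        leaflet=leaflet,
        species=species,
        fractions=fractions,
        raw_pairs=pair_counts,
        n_frames=len(frames),
        parameters=params,
    )


def lateral_rdf(
    traj_or_frames,
    center,
    target_species: str,
    bin_width: float = 1.0,
    r_max: float | None = None,
    leaflet: str | None = None,
) -> pd.DataFrame:
    """2-D radial distribution function of lipids around centres.

    ``center`` is ``"protein"`` (per-protein lateral centre of geometry,
    averaged over proteins), a species name (head centroids), or an
    explicit (m, 2) array of lateral points used in every frame.
    ``g(r) -> 1`` at large r for random placement.
    """
    frames = _frames_of(traj_or_frames, None)
    box = frames[0].box
    half = min(box[0], box[1]) / 2
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the smallest lateral box edge ({half:.1f})")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    norm = 0.0  # accumulated n_centers * rho per frame
    for f in frames:
        t_sel = f.select_molecules(species=target_species, leaflet=leaflet, lipids_only=True)
        targets = f.head_centroids(t_sel)[:, :2]
        exclude_self = False
        if isinstance(center, str) and center == "protein":
            p_sel = f.select_molecules(species=PROTEIN_SPECIES)
            if len(p_sel) == 0:
                raise ValueError("no protein molecules in frame")
            pos, owner = f.bead_positions(p_sel, "head")
            centers = np.array([pos[owner == i, :2].mean(axis=0) for i in p_sel])
        elif isinstance(center, str):
            c_sel = f.select_molecules(species=center, leaflet=leaflet, lipids_only=True)
            if len(c_sel) == 0:
                raise ValueError(f"no centre molecules of species {center!r}")
            centers = f.head_centroids(c_sel)[:, :2]
            exclude_self = center == target_species
        else:
            centers = np.atleast_2d(np.asarray(center, dtype=float))
        if len(targets) == 0:
            continue
        d = centers[:, None, :] - targets[None, :, :]
        d = min_image_displacement(d, box[:2], mode="xy")
        r = np.hypot(d[..., 0], d[..., 1]).ravel()
        if exclude_self:
            r = r[r > 1e-9]
        counts += np.histogram(r, bins=edges)[0]
        area = box[0] * box[1]
        n_t = len(targets) - (1 if exclude_self else 0)
        norm += len(centers) * (n_t / area)
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts / (shell * max(norm, 1e-300))
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"r_A": r_mid, "g": g, "count": counts})


def residue_lipid_contacts(
    traj_or_frames,
    lipid_species: str,
    lipid_beads: Sequence[str],
    params: ContactParameters | None = None,
) -> pd.DataFrame:
    """Per-residue protein-lipid contact statistics.

    For each protein residue: the time-mean number of selected lipid
    beads within the protein contact cutoff (default 6 A) and the
    persistence (fraction of frames with at least one contact).
    Residues with persistence > 0.5 are flagged persistent.
    """
    params = params or ContactParameters()
    frames = _frames_of(traj_or_frames, params)
    f0 = frames[0]
    if f0.residue_ids is None:
        raise ValueError("protein beads carry no residue labels")
    prot_beads = f0.species[f0.mol_index].astype(str) == PROTEIN_SPECIES
    resids = np.unique(f0.residue_ids[prot_beads])
    if len(resids) == 0:
        raise ValueError("no protein residues in frame")
    total = {int(r): 0.0 for r in resids}
    hits = {int(r): 0 for r in resids}
    for f in frames:
        pmask = f.species[f.mol_index].astype(str) == PROTEIN_SPECIES
        lmask = (f.species[f.mol_index].astype(str) == lipid_species) & np.isin(
            f.bead_names.astype(str), list(lipid_beads)
        )
        if not lmask.any():
            raise ValueError(f"selector {list(lipid_beads)} matches no {lipid_species} beads")
        ppos = wrap_coords(f.coords[pmask], f.box)
        lpos = wrap_coords(f.coords[lmask], f.box)
        presid = f.residue_ids[pmask]
        tree = cKDTree(lpos, boxsize=f.box)
        n_near = tree.query_ball_point(ppos, params.protein_contact_cutoff, return_length=True)
        per_res: dict[int, int] = {}
        for rid, c in zip(presid, n_near):
            per_res[int(rid)] = per_res.get(int(rid), 0) + int(c)
        for rid in total:
            c = per_res.get(rid, 0)
            total[rid] += c
            hits[rid] += 1 if c > 0 else 0
    n = len(frames)
    rows = [
        {
            "residue": rid,
            "mean_contacts": total[rid] / n,
            "persistence": hits[rid] / n,
            "persistent": hits[rid] / n > 0.5,
        }
        for rid in sorted(total)
    ]
    return pd.DataFrame(rows)
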