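"""Core membrane containers: frames, trajectories, compositions, leaflets.

Internal units are Angstrom for length and nanoseconds for time; GRO I/O
converts from/to nm at the boundary.  A :class:`MembraneFrame` stores all
beads of one snapshot in flat numpy arrays with contiguous per-molecule
blocks, which keeps the analysis code vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .species import PROTEIN_SPECIES, get_species, is_lipid

__all__ = [
    "MembraneFrame",
    "Trajectory",
    "CompositionSpec",
    "assign_leaflets",
    "composition_counts",
    "largest_remainder_counts",
    "LEAFLET_TAGS",
]

LEAFLET_TAGS = ("outer", "inner", "core", "protein", "none")


@dataclass
class MembraneFrame:
    """One membrane snapshot: beads grouped into molecules, plus box and tags.

    Attributes
    ----------
    box : (3,) float array, Angstrom (orthorhombic edges)
    species : (n_mol,) object array of species names ("PROT" for proteins)
    mol_ids : (n_mol,) int array, unique molecule identifiers
    leaflets : (n_mol,) object array with values from ``LEAFLET_TAGS``
    coords : (n_beads, 3) float array, Angstrom
    bead_names : (n_beads,) object array
    mol_start : (n_mol + 1,) int offsets; beads of molecule i occupy
        ``coords[mol_start[i]:mol_start[i+1]]``
    residue_ids : optional (n_beads,) int array (protein residue indices)
    velocities : optional (n_beads, 3) float array (Angstrom/ps, from GRO)
    time : float, ns
    """

    box: np.ndarray
    species: np.ndarray
    mol_ids: np.ndarray
    leaflets: np.ndarray
    coords: np.ndarray
    bead_names: np.ndarray
    mol_start: np.ndarray
    residue_ids: np.ndarray | None = None
    velocities: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.mol_start = np.asarray(self.mol_start, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=object)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        self.mol_ids = np.asarray(self.mol_ids, dtype=np.int64)
        self.leaflets = np.asarray(self.leaflets, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.box.shape != (3,) or np.any(self.box <= 0) or not np.all(np.isfinite(self.box)):
            raise ValueError("box must be 3 positive finite edge lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite bead coordinates")
        n_mol = len(self.species)
        if len(self.mol_start) != n_mol + 1 or self.mol_start[0] != 0 or self.mol_start[-1] != len(self.coords):
            raise ValueError("mol_start offsets inconsistent with coords")
        if np.any(np.diff(self.mol_start) <= 0):
            raise ValueError("every molecule needs at least one bead")
        if len(np.unique(self.mol_ids)) != n_mol:
            raise ValueError("molecule ids must be unique")
        unknown = {s for s in self.species if s != PROTEIN_SPECIES and not is_lipid(s)}
        if unknown:
            raise ValueError(f"species not in registry: {sorted(unknown)}")
        bad = set(self.leaflets) - set(LEAFLET_TAGS)
        if bad:
            raise ValueError(f"invalid leaflet tags: {sorted(bad)}")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_molecules(
        cls,
        molecules: Sequence[tuple],
        box,
        time: float = 0.0,
        velocities: Sequence[np.ndarray] | None = None,
    ) -> "MembraneFrame":
        """Build a frame from ``(species, mol_id, leaflet, coords, bead_names[, resids])`` tuples."""
        species, mol_ids, leaflets, coord_blocks, name_blocks, resid_blocks = [], [], [], [], [], []
        have_resids = False
        for mol in molecules:
            sp, mid, leaf, xyz, names = mol[:5]
            resids = mol[5] if len(mol) > 5 else None
            xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
            if len(names) != len(xyz):
                raise ValueError(f"molecule {mid}: {len(names)} bead names but {len(xyz)} coordinates")
            species.append(sp)
            mol_ids.append(mid)
            leaflets.append(leaf)
            coord_blocks.append(xyz)
            name_blocks.append(np.asarray(names, dtype=object))
            if resids is not None:
                have_resids = True
            resid_blocks.append(resids if resids is not None else np.zeros(len(xyz), dtype=np.int64))
        counts = np.array([len(b) for b in coord_blocks], dtype=np.int64)
        mol_start = np.concatenate([[0], np.cumsum(counts)])
        return cls(
            box=box,
            species=np.array(species, dtype=object),
            mol_ids=np.array(mol_ids, dtype=np.int64),
            leaflets=np.array(leaflets, dtype=object),
            coords=np.concatenate(coord_blocks) if coord_blocks else np.zeros((0, 3)),
            bead_names=np.concatenate(name_blocks) if name_blocks else np.array([], dtype=object),
            mol_start=mol_start,
            residue_ids=np.concatenate(resid_blocks).astype(np.int64) if have_resids else None,
            velocities=np.concatenate([np.atleast_2d(v) for v in velocities]) if velocities else None,
            time=time,
        )

    # -- basic accessors -------------------------------------------------
    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def mol_index(self) -> np.ndarray:
        """(n_beads,) molecule row index of every bead."""
        cached = getattr(self, "_mol_index", None)
        if cached is None or len(cached) != self.n_beads:
            cached = np.repeat(np.arange(self.n_molecules), np.diff(self.mol_start))
            self._mol_index = cached
        return cached

    def mol_coords(self, i: int) -> np.ndarray:
        return self.coords[self.mol_start[i] : self.mol_start[i + 1]]

    def mol_bead_names(self, i: int) -> np.ndarray:
        return self.bead_names[self.mol_start[i] : self.mol_start[i + 1]]

    def select_molecules(
        self,
        species: str | Iterable[str] | None = None,
        leaflet: str | Iterable[str] | None = None,
        exclude_species: Iterable[str] = (),
        lipids_only: bool = False,
    ) -> np.ndarray:
        """Indices of molecules matching the species/leaflet filters."""
        mask = np.ones(self.n_molecules, dtype=bool)
        if species is not None:
            wanted = {species} if isinstance(species, str) else set(species)
            mask &= np.isin(self.species.astype(str), list(wanted))
        if leaflet is not None and leaflet != "all":
            wanted = {leaflet} if isinstance(leaflet, str) else set(leaflet)
            mask &= np.isin(self.leaflets.astype(str), list(wanted))
        if exclude_species:
            mask &= ~np.isin(self.species.astype(str), list(exclude_species))
        if lipids_only:
            mask &= self.species.astype(str) != PROTEIN_SPECIES
        return np.flatnonzero(mask)

    # -- role-based bead lookups ----------------------------------------
    def _role_names(self, sp_name: str, role: str) -> tuple[str, ...]:
        sp = get_species(sp_name)
        if role == "head":
            return sp.head_beads
        if role == "linker":
            return sp.linker_beads
        if role == "interface":
            return (sp.interface_bead,)
        raise ValueError(f"unknown bead role {role!r}")

    def bead_positions(self, mol_sel: np.ndarray, role: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions of role beads of the selected molecules.

        Returns ``(positions (m, 3), owner (m,))`` where ``owner`` is the
        molecule row index of each bead.
        """
        mol_sel = np.asarray(mol_sel)
        in_sel = np.zeros(self.n_molecules, dtype=bool)
        in_sel[mol_sel] = True
        bead_species = self.species[self.mol_index].astype(str)
        bead_in_sel = in_sel[self.mol_index]
        mask = np.zeros(self.n_beads, dtype=bool)
        for sp_name in dict.fromkeys(self.species[mol_sel].astype(str)):
            if sp_name == PROTEIN_SPECIES:
                sub = bead_in_sel & (bead_species == PROTEIN_SPECIES)
            else:
                names = self._role_names(sp_name, role)
                sub = bead_in_sel & (bead_species == sp_name) & np.isin(self.bead_names.astype(str), names)
            mask |= sub
        return self.coords[mask], self.mol_index[mask]

    def head_centroids(self, mol_sel: np.ndarray) -> np.ndarray:
        """Head-bead centroid of each selected molecule (order of mol_sel)."""
        pos, owner = self.bead_positions(mol_sel, "head")
        sums = np.zeros((self.n_molecules, 3))
        np.add.at(sums, owner, pos)
        counts = np.bincount(owner, minlength=self.n_molecules).astype(float)
        counts[counts == 0] = np.nan
        return (sums / counts[:, None])[mol_sel]

    def reference_z(self, mol_sel: np.ndarray) -> np.ndarray:
        """Leaflet reference z: head centroid (ROH for cholesterol)."""
        return self.head_centroids(mol_sel)[:, 2]

    def copy(self) -> "MembraneFrame":
        return MembraneFrame(
            box=self.box.copy(),
            species=self.species.copy(),
            mol_ids=self.mol_ids.copy(),
            leaflets=self.leaflets.copy(),
            coords=self.coords.copy(),
            bead_names=self.bead_names.copy(),
            mol_start=self.mol_start.copy(),
            residue_ids=None if self.residue_ids is None else self.residue_ids.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            time=self.time,
        )


@dataclass
class Trajectory:
    """Time-ordered frames with consistent molecule indexing."""

    frames: list[MembraneFrame]
    dt: float | None = None  # ns between stored frames; inferred if None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        times = np.array([f.time for f in self.frames], dtype=float)
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        first = self.frames[0]
        for k, f in enumerate(self.frames[1:], start=1):
            if f.n_molecules != first.n_molecules or not np.array_equal(f.mol_ids, first.mol_ids):
                raise ValueError(f"frame {k}: molecule count/ordering differs from frame 0")
        if self.dt is None and len(times) > 1:
            self.dt = float(np.median(np.diff(times)))

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def window(self, start: float | None = None, end: float | None = None, stride: float | None = None):
        """Frames with start <= t <= end, subsampled to ~``stride`` ns."""
        t = self.times
        mask = np.ones(len(t), dtype=bool)
        if start is not None:
            mask &= t >= start - 1e-9
        if end is not None:
            mask &= t <= end + 1e-9
        idx = np.flatnonzero(mask)
        if stride is not None and len(idx) > 1:
            dt = self.dt or float(np.median(np.diff(t[idx])))
            step = max(1, int(round(stride / dt)))
            idx = idx[::step]
        return [self.frames[i] for i in idx]


@dataclass
class CompositionSpec:
    """Per-leaflet target species fractions for the membrane builder."""

    outer: dict[str, float]
    inner: dict[str, float]
    total_lipids: int | None = None
    cholesterol_split: str = "equal"

    def __post_init__(self) -> None:
        for label, frac in (("outer", self.outer), ("inner", self.inner)):
            self._validate_leaflet(label, frac)

    @staticmethod
    def _validate_leaflet(label: str, fractions: dict[str, float]) -> None:
        if any(v < 0 for v in fractions.values()):
            raise ValueError(f"{label} leaflet: negative fraction")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{label} leaflet fractions sum to {total}, expected 1")
        for name in fractions:
            get_species(name)  # raises for unknown species

    def leaflet(self, which: str) -> dict[str, float]:
        if which == "outer":
            return self.outer
        if which == "inner":
            return self.inner
        raise ValueError(f"unknown leaflet {which!r}")


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer counts from fractions by largest-remainder rounding.

    Remainder ties are broken by species name order so the rounding is
    deterministic; every count is within one lipid of ``fraction * total``.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    names = sorted(fractions)
    exact = np.array([fractions[n] * total for n in names])
    if abs(exact.sum() - total) > 1e-6:
        raise ValueError("fractions must sum to 1")
    base = np.floor(exact).astype(int)
    short = int(round(total - base.sum()))
    remainders = exact - base
    # stable sort on -remainder keeps name order within ties
    order = np.argsort(-remainders, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {n: int(c) for n, c in zip(names, base)}


def _lateral_cells(xy: np.ndarray, box: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    nx, ny = grid
    ix = np.floor(np.mod(xy[:, 0], box[0]) / box[0] * nx).astype(int) % nx
    iy = np.floor(np.mod(xy[:, 1], box[1]) / box[1] * ny).astype(int) % ny
    return ix * ny + iy


def assign_leaflets(
    frame: MembraneFrame,
    core_half_width: float = 10.0,
    grid: tuple[int, int] = (4, 4),
) -> MembraneFrame:
    """Tag each lipid outer/inner/core relative to the local midplane.

    The midplane is estimated per lateral grid cell (default 4x4) as the
    mean z of all lipid linker beads in that cell, so the assignment
    remains correct for undulating membranes.  A lipid is ``outer`` when
    its reference bead (head centroid; ROH for cholesterol) lies more
    than ``core_half_width`` above the midplane, ``inner`` when more than
    that below, and ``core`` otherwise.  Protein tags are preserved.
    """
    lipids = frame.select_molecules(lipids_only=True)
    if len(lipids) == 0:
        raise ValueError("frame contains no lipid molecules")
    # cholesterol is excluded from the midplane estimate: it has no
    # glycerol/amide linker and exchanges between leaflets, so its ROH
    # position would bias the reference plane it is judged against
    anchors = frame.select_molecules(lipids_only=True, exclude_species=("CHOL",))
    if len(anchors) == 0:
        anchors = lipids
    linker_pos, _ = frame.bead_positions(anchors, "linker")
    cells = _lateral_cells(linker_pos[:, :2], frame.box, grid)
    n_cells = grid[0] * grid[1]
    z_sum = np.bincount(cells, weights=linker_pos[:, 2], minlength=n_cells)
    z_cnt = np.bincount(cells, minlength=n_cells).astype(float)
    global_mid = linker_pos[:, 2].mean()
    midplane = np.where(z_cnt > 0, z_sum / np.maximum(z_cnt, 1), global_mid)

    ref = frame.head_centroids(lipids)
    ref_cells = _lateral_cells(ref[:, :2], frame.box, grid)
    dz = ref[:, 2] - midplane[ref_cells]

    out = frame.copy()
    tags = np.where(dz > core_half_width, "outer", np.where(dz < -core_half_width, "inner", "core"))
    out.leaflets[lipids] = tags
    return out


def composition_counts(frame: MembraneFrame, leaflet: str = "all") -> dict[str, int]:
    """Exact per-species lipid counts in a leaflet selection."""
    if leaflet not in ("outer", "inner", "core", "all"):
        raise ValueError(f"unknown leaflet label {leaflet!r}")
    sel = frame.select_molecules(leaflet=None if leaflet == "all" else leaflet, lipids_only=True)
    return dict(Counter(str(s) for s in frame.species[sel]))
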