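"""Asymmetric complex membrane construction by editing a POPC template.

The construction mirrors the classical "exchange" protocol: start from a
flat all-POPC bilayer, then per leaflet convert randomly chosen POPC
molecules into the target species.  Same-size or shorter species simply
inherit the POPC bead coordinates (relabelling); larger species are
rigid-superimposed onto the first two tail beads of the chosen POPC;
cholesterol is superimposed onto the head group and the first three
tail beads.  The exchange is one-for-one, so leaflet totals and the
total lipid count never change and both leaflets keep equal lipid
percentages by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, isqrt, sqrt

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import CompositionSpec, MembraneFrame, composition_counts, largest_remainder_counts
from .geometry import wrap_coords
from .species import PROTEIN_SPECIES, get_species
from .templates import Z_LINKER, ideal_tm_helix, species_template

__all__ = [
    "BuildRecipe",
    "ProteinGridSpec",
    "generate_template_bilayer",
    "exchange_lipids",
    "place_protein_grid",
    "replicate_frame",
    "area_per_lipid",
    "build_membrane",
]

# species whose beads are transferred positionally from the chosen POPC
_RELABEL = {"POPE", "POPS", "PPCS"}
# species rigid-superimposed onto the first two tail beads of the POPC
_SUPERIMPOSE = {"DOPC", "DOPE", "DOPS", "PIP2", "GM3"}


@dataclass
class ProteinGridSpec:
    count: int = 16
    spacing: float = 60.0  # Angstrom between grid nodes
    exclusion_radius: float = 3.0  # lipids with any bead this close to a protein bead are removed
    n_res: int = 24


@dataclass
class BuildRecipe:
    composition: CompositionSpec
    seed: int = 0
    n_per_leaflet: int = 750
    apl: float = 53.3  # Angstrom^2 per lipid of the template lattice
    box_z: float = 100.0
    protein: ProteinGridSpec | None = None


def generate_template_bilayer(
    n_per_leaflet: int,
    apl: float = 53.3,
    box_z: float = 100.0,
    seed: int = 0,
    jitter: float = 0.5,
) -> MembraneFrame:
    """Flat all-POPC bilayer on a jittered square lattice.

    The lateral box edge is ``sqrt(n_per_leaflet * apl)``; heads point
    away from the midplane and the two leaflets are mirror images with
    independent lateral jitter.
    """
    if n_per_leaflet < 1:
        raise ValueError("n_per_leaflet must be >= 1")
    if apl <= 0:
        raise ValueError("area per lipid must be positive")
    rng = np.random.default_rng(seed)
    L = sqrt(n_per_leaflet * apl)
    m = ceil(sqrt(n_per_leaflet))
    pitch = L / m
    sites = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"), axis=-1).reshape(-1, 2)
    sites = (sites[:n_per_leaflet] + 0.5) * pitch

    template = species_template("POPC")
    box = np.array([L, L, box_z])
    molecules = []
    mid = 1
    for sign, leaf, offset in ((1.0, "outer", 0.0), (-1.0, "inner", pitch / 2)):
        xy = np.mod(sites + offset + rng.uniform(-jitter, jitter, size=sites.shape), L)
        beads = template.copy()
        beads[:, 2] *= sign
        for k in range(n_per_leaflet):
            xyz = beads + np.array([xy[k, 0], xy[k, 1], sign * Z_LINKER + box_z / 2])
            molecules.append(("POPC", mid, leaf, xyz, list(get_species("POPC").bead_names)))
            mid += 1
    return MembraneFrame.from_molecules(molecules, box=box)


def _rigid_transform(src: np.ndarray, dst: np.ndarray):
    """Least-squares rigid map taking anchor points ``src`` onto ``dst``."""
    src = np.atleast_2d(src)
    dst = np.atleast_2d(dst)
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    with warnings.catch_warnings():
        # collinear anchors leave the roll undefined; any optimum is fine
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(dst - dc, src - sc)
    return lambda pts: rot.apply(pts - sc) + dc


def _convert_molecule(target: str, popc_coords: np.ndarray, popc_names: list[str], upper: bool):
    """Coordinates + bead names for one POPC converted to ``target``."""
    sp = get_species(target)
    names = list(sp.bead_names)
    if target == "POPC":
        return popc_coords, names
    if target in _RELABEL:
        if sp.n_beads > len(popc_coords):
            raise ValueError(f"{target}: relabel target larger than POPC")
        return popc_coords[: sp.n_beads].copy(), names

    tmpl = species_template(sp)
    if not upper:
        tmpl = tmpl * np.array([1.0, 1.0, -1.0])
    name_idx = {n: i for i, n in enumerate(popc_names)}
    popc_sp = get_species("POPC")
    if target == "CHOL":
        # superimpose onto the head group and first three tail beads
        anchors_popc = ["PO4"] + list(popc_sp.tail_beads[0][:3])
        anchors_tmpl = ["ROH", "R1", "R2", "R3"]
    else:
        # superimpose onto the first two tail beads
        anchors_popc = list(popc_sp.tail_beads[0][:2])
        anchors_tmpl = list(sp.tail_beads[0][:2])
    src = tmpl[[names.index(a) for a in anchors_tmpl]]
    dst = popc_coords[[name_idx[a] for a in anchors_popc]]
    return _rigid_transform(src, dst)(tmpl), names


def exchange_lipids(template: MembraneFrame, recipe: BuildRecipe | CompositionSpec, seed: int | None = None) -> MembraneFrame:
    """Convert a POPC template bilayer to the target composition.

    Per leaflet, integer species counts come from largest-remainder
    rounding of the recipe fractions; the POPC molecules to convert are
    drawn uniformly without replacement with a seeded generator, so a
    fixed seed reproduces the membrane bit for bit.
    """
    if isinstance(recipe, BuildRecipe):
        comp = recipe.composition
        seed = recipe.seed if seed is None else seed
    else:
        comp = recipe
        seed = 0 if seed is None else seed
    rng = np.random.default_rng(seed)

    if set(template.species) != {"POPC"}:
        raise ValueError("exchange requires an all-POPC template bilayer")
    if not set(template.leaflets) <= {"outer", "inner"}:
        raise ValueError("template leaflets must be assigned before exchange")

    assignment: dict[int, str] = {}
    for leaf in ("outer", "inner"):
        sel = template.select_molecules(species="POPC", leaflet=leaf)
        counts = largest_remainder_counts(comp.leaflet(leaf), len(sel))
        if sum(counts.values()) != len(sel):
            raise ValueError("target counts exceed available POPC")
        order = rng.permutation(sel)
        pos = 0
        for name in sorted(counts):
            for i in order[pos : pos + counts[name]]:
                assignment[int(i)] = name
            pos += counts[name]

    molecules = []
    for i in range(template.n_molecules):
        target = assignment.get(i, "POPC")
        upper = template.leaflets[i] == "outer"
        xyz, names = _convert_molecule(
            target, template.mol_coords(i), list(template.mol_bead_names(i)), upper
        )
        molecules.append((target, int(template.mol_ids[i]), str(template.leaflets[i]), xyz, names))
    return MembraneFrame.from_molecules(molecules, box=template.box, time=template.time)


def place_protein_grid(
    frame: MembraneFrame,
    n_proteins: int,
    spacing: float,
    exclusion_radius: float = 3.0,
    protein_beads: np.ndarray | None = None,
    protein_resids: np.ndarray | None = None,
    n_res: int = 24,
    dims: tuple[int, int] | None = None,
) -> MembraneFrame:
    """Insert TM proteins on a regular lateral grid and clear clashes.

    The nearest-neighbour centre spacing equals ``spacing`` exactly in
    the returned frame (the grid is centred, and a grid that does not
    fit the periodic box raises).  Lipids with any bead within
    ``exclusion_radius`` of any protein bead are deleted.
    """
    if dims is None:
        s = isqrt(n_proteins)
        if s * s != n_proteins:
            raise ValueError("n_proteins must be a perfect square (or pass dims)")
        dims = (s, s)
    nx, ny = dims
    if nx * ny != n_proteins:
        raise ValueError("dims inconsistent with n_proteins")
    if nx * spacing > frame.box[0] + 1e-9 or ny * spacing > frame.box[1] + 1e-9:
        raise ValueError(
            f"{nx}x{ny} grid at {spacing} A does not fit the {frame.box[0]:.1f}x{frame.box[1]:.1f} A box"
        )
    if protein_beads is None:
        protein_beads = ideal_tm_helix(n_res=n_res)
        protein_beads = protein_beads + np.array([0.0, 0.0, frame.box[2] / 2])
        protein_resids = np.arange(1, n_res + 1)
    protein_beads = np.asarray(protein_beads, dtype=float)
    if protein_resids is None:
        protein_resids = np.arange(1, len(protein_beads) + 1)

    x0 = (frame.box[0] - (nx - 1) * spacing) / 2
    y0 = (frame.box[1] - (ny - 1) * spacing) / 2
    centers = [(x0 + i * spacing, y0 + j * spacing) for i in range(nx) for j in range(ny)]

    lateral_center = protein_beads[:, :2].mean(axis=0)
    next_id = int(frame.mol_ids.max()) + 1 if frame.n_molecules else 1
    molecules = [
        (
            str(frame.species[i]),
            int(frame.mol_ids[i]),
            str(frame.leaflets[i]),
            frame.mol_coords(i),
            list(frame.mol_bead_names(i)),
        )
        for i in range(frame.n_molecules)
    ]
    prot_coords = []
    for cx, cy in centers:
        xyz = protein_beads.copy()
        xyz[:, :2] += np.array([cx, cy]) - lateral_center
        prot_coords.append(xyz)
        molecules.append((PROTEIN_SPECIES, next_id, "protein", xyz, ["BB"] * len(xyz), protein_resids))
        next_id += 1

    out = MembraneFrame.from_molecules(molecules, box=frame.box, time=frame.time)
    if exclusion_radius > 0:
        tree = cKDTree(wrap_coords(np.concatenate(prot_coords), out.box), boxsize=out.box)
        lipid_sel = out.select_molecules(lipids_only=True)
        clash = set()
        bead_mol = out.mol_index
        lipid_mask = np.isin(bead_mol, lipid_sel)
        lipid_beads = wrap_coords(out.coords[lipid_mask], out.box)
        owners = bead_mol[lipid_mask]
        d, _ = tree.query(lipid_beads, k=1, distance_upper_bound=exclusion_radius)
        clash = np.unique(owners[np.isfinite(d)])
        if len(clash):
            keep = np.setdiff1d(np.arange(out.n_molecules), clash)
            molecules = [
                (
                    str(out.species[i]),
                    int(out.mol_ids[i]),
                    str(out.leaflets[i]),
                    out.mol_coords(i),
                    list(out.mol_bead_names(i)),
                    None if out.residue_ids is None else out.residue_ids[out.mol_start[i] : out.mol_start[i + 1]],
                )
                for i in keep
            ]
            out = MembraneFrame.from_molecules(molecules, box=out.box, time=out.time)
    return out


def replicate_frame(frame: MembraneFrame, nx: int, ny: int) -> MembraneFrame:
    """Tile the frame nx-by-ny laterally (genconf-style replication)."""
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    molecules = []
    mid = 1
    for i in range(nx):
        for j in range(ny):
            shift = np.array([i * frame.box[0], j * frame.box[1], 0.0])
            for k in range(frame.n_molecules):
                molecules.append(
                    (
                        str(frame.species[k]),
                        mid,
                        str(frame.leaflets[k]),
                        frame.mol_coords(k) + shift,
                        list(frame.mol_bead_names(k)),
                        None
                        if frame.residue_ids is None
                        else frame.residue_ids[frame.mol_start[k] : frame.mol_start[k + 1]],
                    )
                )
                mid += 1
    box = frame.box * np.array([nx, ny, 1.0])
    return MembraneFrame.from_molecules(molecules, box=box, time=frame.time)


def area_per_lipid(frame: MembraneFrame, leaflet: str) -> float:
    """Lateral box area divided by the lipid count in the leaflet."""
    sel = frame.select_molecules(leaflet=leaflet, lipids_only=True)
    if len(sel) == 0:
        raise ValueError(f"no lipids in leaflet {leaflet!r}")
    return float(frame.box[0] * frame.box[1] / len(sel))


def build_membrane(recipe: BuildRecipe) -> tuple[MembraneFrame, dict]:
    """Template -> exchange -> optional protein grid; returns frame + report."""
    template = generate_template_bilayer(
        recipe.n_per_leaflet, apl=recipe.apl, box_z=recipe.box_z, seed=recipe.seed
    )
    frame = exchange_lipids(template, recipe)
    if recipe.protein is not None:
        p = recipe.protein
        frame = place_protein_grid(
            frame, p.count, p.spacing, exclusion_radius=p.exclusion_radius, n_res=p.n_res
        )
    report = {
        "seed": recipe.seed,
        "box_A": frame.box.tolist(),
        "counts": {leaf: composition_counts(frame, leaf) for leaf in ("outer", "inner", "all")},
        "area_per_lipid_A2": {leaf: area_per_lipid(frame, leaf) for leaf in ("outer", "inner")},
        "n_proteins": int(np.sum(frame.species == PROTEIN_SPECIES)),
    }
    return frame, report
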