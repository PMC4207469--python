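"""Synthetic membrane frames and trajectories with planted ground truth.

Each generator emulates one statistical feature of a CG membrane
trajectory -- random lateral mixing, planted nano-clusters, curvature
coupled composition, Brownian lateral diffusion, or cholesterol
inter-leaflet exchange -- and returns its planted parameters in a
ground-truth manifest, so every analysis module can be validated by
parameter recovery without running molecular dynamics.

Lipids are represented with a reduced bead set (head column, linker
beads, interface bead) that is sufficient for every analysis in the
package; all generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np
from scipy.spatial import cKDTree

from .core import MembraneFrame, Trajectory, largest_remainder_counts
from .geometry import wrap_coords
from .species import get_species

__all__ = [
    "SyntheticSpec",
    "generate",
    "make_random_leaflet",
    "make_clustered_leaflet",
    "make_curved_frame",
    "make_diffusion_trajectory",
    "make_flipflop_trajectory",
    "PackingError",
]

DEFAULT_APL = 90.0  # Angstrom^2 per lipid; keeps hard-core placement feasible
HARD_CORE = 7.0  # Angstrom minimum lateral spacing between lipids
Z_LINKER = 13.0  # linker height above the midplane for synthetic lipids


class PackingError(RuntimeError):
    """Raised when hard-core placement cannot reach the requested density."""


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic system (CLI/config surface).

    ``kind`` selects the generator; ``params`` are passed through to the
    matching ``make_*`` function together with ``seed``.
    """

    kind: str  # random_mixing | planted_clusters | curvature_coupled | diffusion | flipflop
    seed: int = 0
    params: dict = field(default_factory=dict)


def generate(spec: SyntheticSpec):
    dispatch = {
        "random_mixing": make_random_leaflet,
        "planted_clusters": make_clustered_leaflet,
        "curvature_coupled": make_curved_frame,
        "diffusion": make_diffusion_trajectory,
        "flipflop": make_flipflop_trajectory,
    }
    try:
        fn = dispatch[spec.kind]
    except KeyError:
        raise ValueError(f"unknown synthetic kind {spec.kind!r}; known: {sorted(dispatch)}") from None
    return fn(seed=spec.seed, **spec.params)


# ---------------------------------------------------------------------------
# hard-core placement
# ---------------------------------------------------------------------------

def _hardcore_positions(
    n: int,
    box_xy: np.ndarray,
    d_min: float,
    rng: np.random.Generator,
    fixed: np.ndarray | None = None,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform random points with a periodic hard-core minimum spacing.

    Batch random sequential addition: propose candidates uniformly,
    reject those conflicting with accepted points (``fixed`` counts as
    already accepted) or with an earlier surviving candidate of the same
    batch.  Raises :class:`PackingError` when the density is infeasible.
    """
    box_xy = np.asarray(box_xy, dtype=float)
    accepted = np.zeros((0, 2))
    for _ in range(max_rounds):
        need = n - len(accepted)
        if need <= 0:
            return accepted
        m = max(64, int(need * 2.5))
        cand = rng.uniform(0.0, box_xy, size=(m, 2))
        blockers = [p for p in (fixed, accepted) if p is not None and len(p)]
        if blockers:
            tree = cKDTree(np.concatenate(blockers), boxsize=box_xy)
            d, _ = tree.query(cand, k=1, distance_upper_bound=d_min)
            cand = cand[~np.isfinite(d)]
        if len(cand) > 1:
            pairs = cKDTree(cand, boxsize=box_xy).query_pairs(d_min, output_type="ndarray")
            drop = np.zeros(len(cand), dtype=bool)
            for i, j in pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]:
                if not drop[i] and not drop[j]:
                    drop[j] = True
            cand = cand[~drop]
        accepted = np.vstack([accepted, cand[:need]])
    raise PackingError(
        f"could not place {n} points with {d_min} A hard core in a "
        f"{box_xy[0]:.0f}x{box_xy[1]:.0f} A box"
    )


# ---------------------------------------------------------------------------
# reduced bead layout
# ---------------------------------------------------------------------------

def _reduced_layout(sp_name: str) -> tuple[list[str], np.ndarray]:
    """Head + linker + interface beads stacked in a vertical column.

    Offsets are relative to the linker plane (z = 0), head up.
    """
    sp = get_species(sp_name)
    names: list[str] = []
    offs: list[float] = []
    heads = [b for b in sp.head_beads if b not in sp.linker_beads]
    for j, b in enumerate(heads):
        names.append(b)
        offs.append(2.8 * (len(heads) - j))
    for j, b in enumerate(sp.linker_beads):
        names.append(b)
        offs.append(-1.0 * j)
    if sp.interface_bead not in names:
        names.append(sp.interface_bead)
        offs.append(-3.0)
    out = np.zeros((len(names), 3))
    out[:, 2] = offs
    return names, out


def _leaflet_molecules(
    xy: np.ndarray,
    labels: np.ndarray,
    leaflet: str,
    box_z: float,
    start_id: int = 1,
    z_shift: np.ndarray | None = None,
) -> list[tuple]:
    """Reduced-bead molecule tuples for one leaflet."""
    sign = 1.0 if leaflet == "outer" else -1.0
    layouts = {s: _reduced_layout(s) for s in dict.fromkeys(labels)}
    molecules = []
    for k in range(len(xy)):
        names, offs = layouts[labels[k]]
        beads = offs * np.array([1.0, 1.0, sign])
        z0 = sign * Z_LINKER + box_z / 2 + (0.0 if z_shift is None else z_shift[k])
        beads = beads + np.array([xy[k, 0], xy[k, 1], z0])
        molecules.append((labels[k], start_id + k, leaflet, beads, names))
    return molecules


def _species_labels(composition: dict[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    counts = largest_remainder_counts(composition, n)
    labels = np.repeat([s for s in sorted(counts)], [counts[s] for s in sorted(counts)])
    return rng.permutation(labels)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_random_leaflet(
    composition: dict[str, float],
    n: int,
    apl: float = DEFAULT_APL,
    hard_core: float = HARD_CORE,
    seed: int = 0,
    leaflet: str = "outer",
    box_z: float = 100.0,
    time: float = 0.0,
) -> MembraneFrame:
    """One leaflet of uniformly mixed lipids (the random-mixing null).

    Positions are uniform with a periodic hard-core minimum spacing and
    species labels are a uniform random permutation of the integer
    composition counts, so any contact statistic computed on the result
    has the fully-mixed expectation (1/k fractional interactions for k
    species after abundance correction).
    """
    rng = np.random.default_rng(seed)
    L = sqrt(n * apl)
    box = np.array([L, L, box_z])
    xy = _hardcore_positions(n, box[:2], hard_core, rng)
    labels = _species_labels(composition, n, rng)
    molecules = _leaflet_molecules(xy, labels, leaflet, box_z)
    return MembraneFrame.from_molecules(molecules, box=box, time=time)


def stack_leaflets(outer: MembraneFrame, inner: MembraneFrame) -> MembraneFrame:
    """Merge an outer- and an inner-leaflet frame into one bilayer frame."""
    if not np.allclose(outer.box, inner.box):
        raise ValueError("leaflet frames must share a box")
    molecules = []
    mid = 1
    for f in (outer, inner):
        for i in range(f.n_molecules):
            molecules.append(
                (str(f.species[i]), mid, str(f.leaflets[i]), f.mol_coords(i), list(f.mol_bead_names(i)))
            )
            mid += 1
    return MembraneFrame.from_molecules(molecules, box=outer.box, time=outer.time)


def _disc_offsets(size: int, spacing: float) -> np.ndarray:
    """Sunflower-spiral offsets: ``size`` points with ~``spacing`` neighbours."""
    i = np.arange(size, dtype=float)
    r = spacing * 0.55 * np.sqrt(i)
    theta = i * np.pi * (3.0 - sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_clustered_leaflet(
    target_species: str = "GM3",
    cluster_sizes: tuple[int, ...] = (10, 25, 50),
    n_singletons: int = 5,
    background: dict[str, float] | None = None,
    n_background: int = 400,
    intra_spacing: float = 8.0,
    min_gap: float = 45.0,
    seed: int = 0,
    leaflet: str = "outer",
    box_z: float = 100.0,
    box_xy: float | None = None,
) -> tuple[MembraneFrame, dict]:
    """Leaflet with the target species planted in compact discs.

    Disc members sit on a sunflower spiral with neighbour spacing well
    below the 15 A clustering cutoff; disc centres and singletons are
    separated by more than ``min_gap`` plus the disc radii, so a density
    cluster search must recover the planted partition exactly.  The
    manifest lists ground-truth cluster membership by molecule id.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    offsets = [_disc_offsets(s, intra_spacing) for s in sizes]
    radii = [float(np.hypot(o[:, 0], o[:, 1]).max()) if len(o) > 1 else 0.0 for o in offsets]
    max_r = max(radii, default=0.0)
    sep = 2 * max_r + min_gap
    n_super = len(sizes) + n_singletons
    if box_xy is None:
        box_xy = max(1.6 * sep * ceil(sqrt(max(n_super, 1))), sqrt(max(n_background, 1) * DEFAULT_APL), 3 * sep)
    box = np.array([box_xy, box_xy, box_z])

    centers = _hardcore_positions(n_super, box[:2], sep, rng)
    mid = 1
    target_xy = []
    cluster_members: list[list[int]] = []
    for ci, o in enumerate(offsets):
        pts = np.mod(centers[ci] + o, box_xy)
        ids = list(range(mid, mid + len(pts)))
        cluster_members.append(ids)
        target_xy.append(pts)
        mid += len(pts)
    singleton_ids = list(range(mid, mid + n_singletons))
    if n_singletons:
        target_xy.append(centers[len(sizes) :])
    mid += n_singletons
    target_xy = np.concatenate(target_xy) if target_xy else np.zeros((0, 2))

    labels = np.array([target_species] * len(target_xy), dtype=object)
    molecules = _leaflet_molecules(target_xy, labels, leaflet, box_z, start_id=1)

    if background and n_background:
        bg_xy = _hardcore_positions(n_background, box[:2], HARD_CORE, rng, fixed=target_xy)
        bg_labels = _species_labels(background, n_background, rng)
        molecules += _leaflet_molecules(bg_xy, bg_labels, leaflet, box_z, start_id=mid)

    frame = MembraneFrame.from_molecules(molecules, box=box, time=0.0)
    n_target = len(target_xy)
    manifest = {
        "target_species": target_species,
        "cluster_members": cluster_members,
        "singletons": singleton_ids,
        "cluster_sizes": sizes,
        "n_target": n_target,
        "seed": seed,
        "intra_spacing": intra_spacing,
        "min_gap": min_gap,
    }
    return frame, manifest


def _surface_field(modes: list[tuple[int, int]], box_xy: float):
    """Return s(x, y) = sum of unit sine modes, plus its max |s| on a grid."""

    def s(x, y):
        out = np.zeros_like(np.asarray(x, dtype=float))
        for kx, ky in modes:
            out = out + np.sin(2 * np.pi * (kx * x + ky * y) / box_xy)
        return out

    g = np.linspace(0, box_xy, 257)
    X, Y = np.meshgrid(g, g)
    m = float(np.abs(s(X, Y)).max())
    return s, m if m > 0 else 1.0


def make_curved_frame(
    outer_composition: dict[str, float],
    inner_composition: dict[str, float] | None = None,
    couplings: dict[str, float] | None = None,
    amplitude: float = 20.0,
    modes: tuple[tuple[int, int], ...] = ((1, 0),),
    n_per_leaflet: int = 1280,
    apl: float = DEFAULT_APL,
    seed: int = 0,
    box_z: float = 140.0,
    hard_core: float = HARD_CORE,
) -> tuple[MembraneFrame, dict]:
    """Bilayer with a sinusoidal surface and composition-height coupling.

    The surface is ``amplitude * s(x,y)/max|s|`` for the requested sine
    modes; both leaflets are displaced congruently (constant thickness).
    Species positions are drawn by thinning a uniform proposal with
    intensity ``1 + c * z_hat`` where ``z_hat`` is the surface scaled to
    unit maximum, so ``|c| <= 1`` keeps the intensity non-negative and a
    negative coupling enriches the species in the surface troughs.
    """
    couplings = dict(couplings or {})
    if any(abs(c) > 1 for c in couplings.values()):
        raise ValueError("couplings must satisfy |c| <= 1 (intensity would go negative)")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    L = sqrt(n_per_leaflet * apl)
    box = np.array([L, L, box_z])
    s, m = _surface_field(list(modes), L)

    def z_hat(xy):
        return s(xy[:, 0], xy[:, 1]) / m

    molecules = []
    mid = 1
    for leaf, comp in (("outer", outer_composition), ("inner", inner_composition or outer_composition)):
        counts = largest_remainder_counts(comp, n_per_leaflet)
        placed = np.zeros((0, 2))
        leaf_xy, leaf_labels = [], []
        for sp_name in sorted(counts):
            c = couplings.get(sp_name, 0.0)
            n_s = counts[sp_name]
            pts = np.zeros((0, 2))
            for _ in range(400):
                need = n_s - len(pts)
                if need <= 0:
                    break
                cand = rng.uniform(0.0, L, size=(max(64, need * 4), 2))
                if c != 0.0:
                    accept = rng.uniform(0, 1, len(cand)) < (1 + c * z_hat(cand)) / (1 + abs(c))
                    cand = cand[accept]
                blockers = [p for p in (placed, pts) if len(p)]
                if blockers and len(cand):
                    tree = cKDTree(np.concatenate(blockers), boxsize=box[:2])
                    d, _ = tree.query(cand, k=1, distance_upper_bound=hard_core)
                    cand = cand[~np.isfinite(d)]
                if len(cand) > 1:
                    pairs = cKDTree(cand, boxsize=box[:2]).query_pairs(hard_core, output_type="ndarray")
                    drop = np.zeros(len(cand), dtype=bool)
                    for i, j in pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]:
                        if not drop[i] and not drop[j]:
                            drop[j] = True
                    cand = cand[~drop]
                pts = np.vstack([pts, cand[:need]])
            else:
                raise PackingError(f"could not place {n_s} {sp_name} lipids under coupling {c}")
            placed = np.vstack([placed, pts])
            leaf_xy.append(pts)
            leaf_labels += [sp_name] * n_s
        xy = np.concatenate(leaf_xy)
        labels = np.array(leaf_labels, dtype=object)
        z_shift = amplitude * z_hat(xy)
        molecules += _leaflet_molecules(xy, labels, leaf, box_z, start_id=mid, z_shift=z_shift)
        mid += len(xy)

    frame = MembraneFrame.from_molecules(molecules, box=box, time=0.0)
    manifest = {
        "couplings": couplings,
        "amplitude": amplitude,
        "modes": [list(m_) for m_ in modes],
        "seed": seed,
        "n_per_leaflet": n_per_leaflet,
    }
    return frame, manifest


def _single_bead_frames(
    wrapped: np.ndarray,
    z_levels: np.ndarray,
    labels: np.ndarray,
    leaflets: np.ndarray,
    bead_names: np.ndarray,
    box: np.ndarray,
    times: np.ndarray,
) -> list[MembraneFrame]:
    """Fast construction of single-bead-per-lipid frames (shared layout)."""
    n_mol = wrapped.shape[1]
    mol_ids = np.arange(1, n_mol + 1)
    mol_start = np.arange(n_mol + 1)
    frames = []
    for t in range(len(wrapped)):
        coords = np.column_stack([wrapped[t], z_levels[t] if z_levels.ndim == 2 else z_levels])
        frames.append(
            MembraneFrame(
                box=box,
                species=labels,
                mol_ids=mol_ids,
                leaflets=leaflets,
                coords=coords,
                bead_names=bead_names,
                mol_start=mol_start,
                time=float(times[t]),
            )
        )
    return frames


def make_diffusion_trajectory(
    species_D: dict[str, float],
    n_per_species: int = 500,
    n_frames: int = 5000,
    dt: float = 1.0,
    apl: float = DEFAULT_APL,
    seed: int = 0,
    box_z: float = 100.0,
) -> tuple[Trajectory, dict]:
    """Independent lateral Gaussian random walks per species.

    ``species_D`` maps species name to a diffusion coefficient in cm^2/s;
    each step has per-axis variance ``2*D*dt`` (lateral MSD slope 4*D).
    Frames store wrapped coordinates (one head bead per lipid); the
    manifest carries the exact unwrapped walk for oracle comparisons.
    """
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    if any(D < 0 for D in species_D.values()):
        raise ValueError("diffusion coefficients must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(species_D)
    n_mol = n_per_species * len(names)
    L = sqrt(max(n_mol, 1) * apl)
    box = np.array([L, L, box_z])

    labels = np.array([s for s in names for _ in range(n_per_species)], dtype=object)
    leaflets = np.array(["outer"] * n_mol, dtype=object)
    bead_names = np.array([get_species(s).head_beads[0] for s in labels], dtype=object)

    start = rng.uniform(0.0, L, size=(n_mol, 2))
    unwrapped = np.empty((n_frames, n_mol, 2))
    unwrapped[0] = start
    for si, s in enumerate(names):
        D_a2ns = species_D[s] * 1e7  # cm^2/s -> A^2/ns
        sigma = sqrt(2.0 * D_a2ns * dt)
        block = slice(si * n_per_species, (si + 1) * n_per_species)
        steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_per_species, 2)) if sigma > 0 else np.zeros(
            (n_frames - 1, n_per_species, 2)
        )
        unwrapped[1:, block] = start[block] + np.cumsum(steps, axis=0)

    wrapped = np.mod(unwrapped, L)
    z_levels = np.full(n_mol, Z_LINKER + box_z / 2)
    times = np.arange(n_frames) * dt
    frames = _single_bead_frames(wrapped, z_levels, labels, leaflets, bead_names, box, times)
    manifest = {
        "species_D_cm2s": dict(species_D),
        "dt_ns": dt,
        "unwrapped": unwrapped,
        "labels": labels,
        "seed": seed,
    }
    return Trajectory(frames, dt=dt), manifest


def make_flipflop_trajectory(
    n_chol: int = 100,
    rate: float = 0.14,
    occupancy: tuple[float, float, float] = (0.49, 0.02, 0.49),
    n_frames: int = 1000,
    dt: float = 1.0,
    n_filler_per_leaflet: int = 200,
    apl: float = DEFAULT_APL,
    seed: int = 0,
    box_z: float = 100.0,
    z_noise: float = 1.0,
) -> tuple[Trajectory, dict]:
    """Cholesterol three-state (outer/core/inner) exchange trajectory.

    Cholesterol states follow a discrete-time Markov chain whose
    stationary distribution matches ``occupancy`` and whose expected
    full-crossing rate (outer <-> inner, core passages allowed) summed
    over molecules equals ``rate`` events/ns.  Static phospholipids in
    both leaflets provide the midplane reference.  The manifest lists
    every true crossing event of the simulated chain.
    """
    po, pc, pi = occupancy
    if abs(po + pc + pi - 1.0) > 1e-9 or min(po, pc, pi) < 0:
        raise ValueError("occupancy must be non-negative and sum to 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)

    # detailed-balance chain: core exit rates proportional to the leaflet
    # occupancies; kappa solves the requested total crossing rate.
    if rate > 0:
        if min(po, pc, pi) == 0:
            raise ValueError("non-zero rate requires non-zero occupancy in every state")
        kappa = rate * (po + pi) / (2.0 * n_chol * pc * po * pi)
        a_dt = pc * kappa * dt  # leaflet -> core probability per frame
        b_o = kappa * po * dt  # core -> outer
        b_i = kappa * pi * dt
        if a_dt > 0.5 or (b_o + b_i) > 0.9:
            raise ValueError("rate too high for this frame interval; reduce dt or rate")
    else:
        a_dt = b_o = b_i = 0.0

    OUTER, CORE, INNER = 0, 1, 2
    states = np.empty((n_frames, n_chol), dtype=np.int8)
    states[0] = rng.choice([OUTER, CORE, INNER], size=n_chol, p=[po, pc, pi])
    last_leaflet = np.where(states[0] == CORE, -1, states[0]).astype(np.int8)
    events: list[dict] = []
    for t in range(1, n_frames):
        prev = states[t - 1]
        u = rng.uniform(0, 1, n_chol)
        nxt = prev.copy()
        leaf = prev != CORE
        nxt[leaf & (u < a_dt)] = CORE
        in_core = prev == CORE
        nxt[in_core & (u < b_o)] = OUTER
        nxt[in_core & (u >= b_o) & (u < b_o + b_i)] = INNER
        states[t] = nxt
        entered = (nxt != CORE) & (nxt != prev)
        for m in np.flatnonzero(entered):
            if last_leaflet[m] == -1:
                last_leaflet[m] = nxt[m]
            elif nxt[m] != last_leaflet[m]:
                events.append(
                    {
                        "mol_id": int(m + 1),
                        "frame": int(t),
                        "time_ns": float(t * dt),
                        "direction": "outer->inner" if nxt[m] == INNER else "inner->outer",
                    }
                )
                last_leaflet[m] = nxt[m]

    n_filler = 2 * n_filler_per_leaflet
    n_mol = n_chol + n_filler
    L = sqrt(n_mol * apl)
    box = np.array([L, L, box_z])

    chol_xy = rng.uniform(0.0, L, size=(n_chol, 2))
    z_map = np.array([Z_LINKER, 0.0, -Z_LINKER])
    chol_z = z_map[states] + rng.uniform(-z_noise, z_noise, size=states.shape) + box_z / 2

    # filler on a jittered lattice per leaflet: even lateral coverage keeps
    # the local midplane estimate unbiased in every grid cell
    m_lat = ceil(sqrt(n_filler_per_leaflet))
    sites = np.stack(np.meshgrid(np.arange(m_lat), np.arange(m_lat), indexing="ij"), axis=-1).reshape(-1, 2)
    sites = (sites[:n_filler_per_leaflet] + 0.5) * (L / m_lat)
    filler_xy = np.vstack(
        [np.mod(sites + rng.uniform(-1.0, 1.0, sites.shape), L) for _ in range(2)]
    )
    filler_leaf = np.array(["outer"] * n_filler_per_leaflet + ["inner"] * n_filler_per_leaflet, dtype=object)

    mol_ids = np.arange(1, n_mol + 1)
    popc = get_species("POPC")
    layout_names, layout_offs = _reduced_layout("POPC")
    frames = []
    # static filler beads computed once
    filler_blocks = []
    for k in range(n_filler):
        sign = 1.0 if filler_leaf[k] == "outer" else -1.0
        beads = layout_offs * np.array([1.0, 1.0, sign])
        beads = beads + np.array([filler_xy[k, 0], filler_xy[k, 1], sign * Z_LINKER + box_z / 2])
        filler_blocks.append(beads)
    filler_coords = np.concatenate(filler_blocks)
    filler_names = np.array(layout_names * n_filler, dtype=object)
    n_lay = len(layout_names)

    species_arr = np.array(["CHOL"] * n_chol + ["POPC"] * n_filler, dtype=object)
    leaflets_arr = np.concatenate([np.array(["core"] * n_chol, dtype=object), filler_leaf])
    bead_names = np.concatenate([np.array(["ROH"] * n_chol, dtype=object), filler_names])
    mol_start = np.concatenate([np.arange(n_chol + 1), n_chol + n_lay * np.arange(1, n_filler + 1)])
    times = np.arange(n_frames) * dt
    for t in range(n_frames):
        chol_coords = np.column_stack([chol_xy, chol_z[t]])
        frames.append(
            MembraneFrame(
                box=box,
                species=species_arr,
                mol_ids=mol_ids,
                leaflets=leaflets_arr,
                coords=np.vstack([chol_coords, filler_coords]),
                bead_names=bead_names,
                mol_start=mol_start,
                time=float(times[t]),
            )
        )

    occ_measured = [float(np.mean(states == s)) for s in (OUTER, CORE, INNER)]
    manifest = {
        "rate_events_per_ns": rate,
        "occupancy": list(occupancy),
        "events": events,
        "n_events": len(events),
        "realized_occupancy": occ_measured,
        "states": states,
        "seed": seed,
        "dt_ns": dt,
    }
    return Trajectory(frames, dt=dt), manifest
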