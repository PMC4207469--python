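"""Idealized straight-chain bead templates for lipids and a TM helix.

The builder edits a template POPC bilayer by relabelling or
superimposing these idealized conformers; no simulated snapshot is
needed because every downstream analysis operates on configurations,
not energies.  Templates are head-up with the linker centroid at the
origin; the builder translates them to the lattice site and mirrors
them for the lower leaflet.
"""

from __future__ import annotations

import numpy as np

from .species import LipidSpecies, get_species

__all__ = ["species_template", "ideal_tm_helix", "Z_LINKER"]

Z_LINKER = 13.0  # Angstrom: linker centroid height above the bilayer midplane
_HEAD_SPACING = 2.8
_TAIL_SPACING = 3.0
_CHOL_SPACING = 1.7
_TAIL_X = (-1.5, 1.5)  # lateral offsets of the two chains


def species_template(sp: LipidSpecies | str) -> np.ndarray:
    """(n_beads, 3) idealized coordinates ordered like ``sp.bead_names``.

    Head beads stack upward from the linker plane, tail beads downward;
    two-chain lipids put their chains at x = -1.5 and +1.5 Angstrom.
    Cholesterol uses a tighter ring spacing so the molecule spans about
    12 Angstrom like the CG sterol.
    """
    sp = get_species(sp) if isinstance(sp, str) else sp
    tail_spacing = _CHOL_SPACING if sp.name == "CHOL" else _TAIL_SPACING
    pos: dict[str, np.ndarray] = {}

    # linker beads side by side at z = 0 (single linker sits on the axis)
    lx = [0.0] if len(sp.linker_beads) == 1 else list(_TAIL_X[: len(sp.linker_beads)])
    for x, name in zip(lx, sp.linker_beads):
        pos[name] = np.array([x, 0.0, 0.0])

    # head beads stack upward, first bead topmost
    heads = [b for b in sp.head_beads if b not in pos]
    for j, name in enumerate(heads):
        pos[name] = np.array([0.0, 0.0, _HEAD_SPACING * (len(heads) - j)])

    # tails stack downward under their linker
    for ti, tail in enumerate(sp.tail_beads):
        x = lx[ti % len(lx)]
        depth = 0
        for name in tail:
            if name in pos:
                continue
            depth += 1
            pos[name] = np.array([x, 0.0, -tail_spacing * depth])

    return np.array([pos[b] for b in sp.bead_names])


def ideal_tm_helix(n_res: int = 24, rise: float = 1.5, radius: float = 2.3, twist_deg: float = 100.0) -> np.ndarray:
    """Backbone-bead coordinates of an idealized membrane-spanning helix.

    One bead per residue on an alpha-helical spiral (1.5 Angstrom rise,
    100 degree twist), centred on z = 0 so the default 24 residues span
    ~36 Angstrom, enough to cross a CG bilayer.
    """
    if n_res < 1:
        raise ValueError("helix needs at least one residue")
    i = np.arange(n_res)
    theta = np.deg2rad(twist_deg) * i
    z = rise * i
    xyz = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    xyz[:, 2] -= xyz[:, 2].mean()
    return xyz
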