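"""GRO coordinate I/O (fixed-column GROMACS dialect) and trajectories.

Files store nanometres; the package works in Angstrom, so coordinates
are scaled by 10 at this boundary.  Molecules are inferred from runs of
identical (residue id, residue name); multi-frame GRO files (frames
concatenated, as written by trjconv) are supported for trajectories.
Protein molecules are written with residue name ``PROT``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import MembraneFrame, Trajectory
from .species import PROTEIN_SPECIES, get_species, is_lipid

__all__ = ["read_gro", "write_gro", "read_frames", "read_trajectory", "write_trajectory"]

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


class GroParseError(ValueError):
    pass


def _parse_frame(lines: list[str], offset: int, path: str) -> tuple[MembraneFrame, int]:
    """Parse one frame starting at ``offset``; returns (frame, next offset)."""
    if offset + 2 > len(lines):
        raise GroParseError(f"{path}: truncated file at line {offset + 1}")
    title = lines[offset].rstrip("\n")
    m = _TIME_RE.search(title)
    time_ns = float(m.group(1)) / 1000.0 if m else 0.0  # GRO titles carry t= in ps
    try:
        natoms = int(lines[offset + 1].strip())
    except ValueError:
        raise GroParseError(f"{path}: line {offset + 2}: atom count is not an integer") from None
    end = offset + 2 + natoms
    if end + 1 > len(lines):
        raise GroParseError(
            f"{path}: header declares {natoms} atoms but the file ends at line {len(lines)} "
            f"(expected box line at line {end + 1})"
        )
    resids = np.empty(natoms, dtype=np.int64)
    resnames = np.empty(natoms, dtype=object)
    names = np.empty(natoms, dtype=object)
    coords = np.empty((natoms, 3))
    velocities = np.zeros((natoms, 3))
    has_vel = False
    for k in range(natoms):
        ln = lines[offset + 2 + k]
        lineno = offset + 3 + k
        try:
            resids[k] = int(ln[0:5])
            resnames[k] = ln[5:10].strip()
            names[k] = ln[10:15].strip()
            coords[k] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        except (ValueError, IndexError):
            raise GroParseError(f"{path}: line {lineno}: malformed atom record") from None
        if len(ln.rstrip("\n")) >= 68:
            try:
                velocities[k] = (float(ln[44:52]), float(ln[52:60]), float(ln[60:68]))
                has_vel = True
            except ValueError:
                pass
    box_fields = lines[end].split()
    try:
        box_vals = [float(v) for v in box_fields]
    except ValueError:
        raise GroParseError(f"{path}: line {end + 1}: malformed box line") from None
    if len(box_vals) < 3:
        raise GroParseError(f"{path}: line {end + 1}: box line needs 3 edge lengths")
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise GroParseError(f"{path}: line {end + 1}: triclinic boxes are not supported")
    box = np.array(box_vals[:3]) * 10.0

    # group beads into molecules at changes of (resid, resname)
    breaks = [0]
    for k in range(1, natoms):
        if resids[k] != resids[k - 1] or resnames[k] != resnames[k - 1]:
            breaks.append(k)
    breaks.append(natoms)
    molecules = []
    vel_blocks = []
    for mi in range(len(breaks) - 1):
        a, b = breaks[mi], breaks[mi + 1]
        resname = str(resnames[a]).upper()
        if resname == PROTEIN_SPECIES:
            sp, leaf = PROTEIN_SPECIES, "protein"
        elif is_lipid(resname):
            sp, leaf = get_species(resname).name, "none"
        else:
            raise GroParseError(f"{path}: line {offset + 3 + a}: unknown residue name {resnames[a]!r}")
        molecules.append((sp, mi + 1, leaf, coords[a:b] * 10.0, list(names[a:b])))
        vel_blocks.append(velocities[a:b] * 10.0)
    frame = MembraneFrame.from_molecules(
        molecules, box=box, time=time_ns, velocities=vel_blocks if has_vel else None
    )
    return frame, end + 1


def read_gro(path: str | Path) -> MembraneFrame:
    """Read the first (or only) frame of a GRO file."""
    lines = Path(path).read_text().splitlines()
    frame, _ = _parse_frame(lines, 0, str(path))
    return frame


def _format_frame(frame: MembraneFrame) -> str:
    out = [f"membranekit frame t= {frame.time * 1000.0:.3f}", f"{frame.n_beads:>5d}"]
    vel = frame.velocities
    atom = 0
    for i in range(frame.n_molecules):
        resid = (i + 1) % 100000
        resname = str(frame.species[i])[:5]
        for name, xyz in zip(frame.mol_bead_names(i), frame.mol_coords(i)):
            atom += 1
            line = f"{resid:>5d}{resname:<5s}{str(name)[:5]:>5s}{atom % 100000:>5d}" + "".join(
                f"{v / 10.0:8.3f}" for v in xyz
            )
            if vel is not None:
                line += "".join(f"{v / 10.0:8.4f}" for v in vel[atom - 1])
            out.append(line)
    out.append(" ".join(f"{v / 10.0:10.5f}" for v in frame.box))
    return "\n".join(out) + "\n"


def write_gro(frame: MembraneFrame, path: str | Path, append: bool = False) -> None:
    """Write a frame in fixed-column GRO format (nm in file)."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(_format_frame(frame))


def write_trajectory(traj: Trajectory | Iterable[MembraneFrame], path: str | Path) -> None:
    """Write frames as a concatenated multi-frame GRO file."""
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(_format_frame(frame))


def read_frames(paths: str | Path | Sequence[str | Path], dt: float | None = None) -> list[MembraneFrame]:
    """Read frames from one multi-frame GRO or several GRO files.

    Times come from the ``t=`` fields when present, otherwise ``dt``
    (default 1 ns) spaces the frames.
    """
    if isinstance(paths, (str, Path)):
        lines = Path(paths).read_text().splitlines()
        frames = []
        offset = 0
        while offset < len(lines):
            frame, offset = _parse_frame(lines, offset, str(paths))
            frames.append(frame)
    else:
        frames = [read_gro(p) for p in paths]
    times = [f.time for f in frames]
    if len(frames) > 1 and len(set(times)) != len(times):
        step = dt if dt is not None else 1.0
        for k, f in enumerate(frames):
            f.time = k * step
    return frames


def read_trajectory(paths: str | Path | Sequence[str | Path], dt: float | None = None) -> Trajectory:
    """Read a trajectory (frames sharing molecule count and ordering)."""
    frames = read_frames(paths, dt=dt)
    first = frames[0]
    for k, f in enumerate(frames[1:], start=1):
        if f.n_beads != first.n_beads or not np.array_equal(f.species, first.species):
            raise GroParseError(f"frame {k}: molecule ordering differs from frame 0")
    return Trajectory(frames, dt=dt)
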