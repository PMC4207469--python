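"""Registry of coarse-grained lipid species.

Each species is described by its ordered bead list plus three functional
bead subsets that the analyses rely on:

* ``head_beads`` -- the polar head group; its centroid is the per-lipid
  point used for clustering, grid binning and leaflet assignment.
* ``linker_beads`` -- the glycerol-ester (GL1/GL2) or amide (AM1/AM2)
  moiety that sits at the head/tail interface; lipid-lipid contacts are
  defined between linker beads.
* ``interface_bead`` -- the first tail bead adjacent to the head group;
  its z coordinate defines the local bilayer surface height.

Cholesterol is special: its hydroxyl bead (ROH) serves as head, linker
and leaflet reference all at once, because the molecule has no glycerol
backbone and readily crosses between leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LipidSpecies", "REGISTRY", "get_species", "is_lipid", "PROTEIN_SPECIES"]

PROTEIN_SPECIES = "PROT"


@dataclass(frozen=True)
class LipidSpecies:
    """Static description of one CG lipid type."""

    name: str
    bead_names: tuple[str, ...]
    head_beads: tuple[str, ...]
    linker_beads: tuple[str, ...]
    interface_bead: str
    tail_beads: tuple[tuple[str, ...], ...]
    net_charge: int = 0

    def __post_init__(self) -> None:
        beads = set(self.bead_names)
        for group, label in (
            (self.head_beads, "head_beads"),
            (self.linker_beads, "linker_beads"),
            ((self.interface_bead,), "interface_bead"),
        ):
            missing = set(group) - beads
            if missing:
                raise ValueError(f"{self.name}: {label} {sorted(missing)} not in bead_names")
        for tail in self.tail_beads:
            if len(tail) < 1:
                raise ValueError(f"{self.name}: every tail must have at least one bead")
            if set(tail) - beads:
                raise ValueError(f"{self.name}: tail beads missing from bead_names")
        if len(set(self.bead_names)) != len(self.bead_names):
            raise ValueError(f"{self.name}: duplicate bead names")

    @property
    def tail_lengths(self) -> tuple[int, ...]:
        return tuple(len(t) for t in self.tail_beads)

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)


def _glycerophospholipid(name: str, head_bead: str, tails, charge: int = 0) -> LipidSpecies:
    head = (head_bead, "PO4")
    linker = ("GL1", "GL2")
    beads = head + linker + tuple(b for t in tails for b in t)
    return LipidSpecies(
        name=name,
        bead_names=beads,
        head_beads=head,
        linker_beads=linker,
        interface_bead=tails[0][0],
        tail_beads=tuple(tuple(t) for t in tails),
        net_charge=charge,
    )


# Palmitoyl-oleoyl tails: the sn-2 oleoyl chain carries one unsaturated bead.
_PO_TAILS = (("C1A", "D2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))
# Di-oleoyl: both chains unsaturated.
_DO_TAILS = (("C1A", "D2A", "C3A", "C4A"), ("C1B", "D2B", "C3B", "C4B"))
# Ceramide tails shared by sphingomyelin and GM3: two 4-bead tails, the
# first sphingosine bead unsaturated.
_SM_TAILS = (("T1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))
# PIP2 carries a 4-bead and a 5-bead unsaturated tail.
_PIP2_TAILS = (("C1A", "D2A", "C3A", "C4A"), ("C1B", "D2B", "C3B", "C4B", "C5B"))

_SPECIES = [
    _glycerophospholipid("POPC", "NC3", _PO_TAILS),
    _glycerophospholipid("POPE", "NH3", _PO_TAILS),
    _glycerophospholipid("POPS", "CNO", _PO_TAILS, charge=-1),
    _glycerophospholipid("DOPC", "NC3", _DO_TAILS),
    _glycerophospholipid("DOPE", "NH3", _DO_TAILS),
    _glycerophospholipid("DOPS", "CNO", _DO_TAILS, charge=-1),
    # PPCS: palmitoyl sphingomyelin; amide linkage instead of glycerol esters.
    LipidSpecies(
        name="PPCS",
        bead_names=("NC3", "PO4", "AM1", "AM2") + tuple(b for t in _SM_TAILS for b in t),
        head_beads=("NC3", "PO4"),
        linker_beads=("AM1", "AM2"),
        interface_bead="T1A",
        tail_beads=_SM_TAILS,
    ),
    # GM3 ganglioside: six-bead trisaccharide head on a ceramide tail.
    LipidSpecies(
        name="GM3",
        bead_names=("GM1", "GM2", "GM3", "GM4", "GM5", "GM6", "AM1", "AM2")
        + tuple(b for t in _SM_TAILS for b in t),
        head_beads=("GM1", "GM2", "GM3", "GM4", "GM5", "GM6"),
        linker_beads=("AM1", "AM2"),
        interface_bead="T1A",
        tail_beads=_SM_TAILS,
        net_charge=-1,
    ),
    # PIP2: inositol ring (RP1-3) with two phosphates; polyanionic.
    LipidSpecies(
        name="PIP2",
        bead_names=("RP1", "RP2", "RP3", "PO1", "PO2", "GL1", "GL2")
        + tuple(b for t in _PIP2_TAILS for b in t),
        head_beads=("RP1", "RP2", "RP3", "PO1", "PO2"),
        linker_beads=("GL1", "GL2"),
        interface_bead="C1A",
        tail_beads=_PIP2_TAILS,
        net_charge=-4,
    ),
    LipidSpecies(
        name="CHOL",
        bead_names=("ROH", "R1", "R2", "R3", "R4", "R5", "C1", "C2"),
        head_beads=("ROH",),
        linker_beads=("ROH",),
        interface_bead="R1",
        tail_beads=(("R1", "R2", "R3", "R4", "R5", "C1", "C2"),),
    ),
]

REGISTRY: dict[str, LipidSpecies] = {sp.name: sp for sp in _SPECIES}

_ALIASES = {"SPH": "PPCS", "SM": "PPCS", "CHOLESTEROL": "CHOL"}


def get_species(name: str) -> LipidSpecies:
    """Look up a species by name (case-insensitive; Sph aliases PPCS)."""
    key = name.upper()
    key = _ALIASES.get(key, key)
    try:
        return REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown lipid species {name!r}; known: {sorted(REGISTRY)}") from None


def is_lipid(name: str) -> bool:
    key = name.upper()
    return _ALIASES.get(key, key) in REGISTRY
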