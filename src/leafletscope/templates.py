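"""Coarse-grained lipid bead templates.

Each lipid species in the Martini-style model is described by a
:class:`LipidTemplate`: which bead is the phosphate (or, for sterols, the
hydroxyl-equivalent anchor), which beads form the headgroup, which bead
terminates each acyl tail, and how many non-headgroup beads a whole molecule
contributes.  The non-headgroup bead count is the divisor used to convert
zone-level bead counts into molar lipid equivalents (headgroups are excluded
because multi-bead headgroups such as PIP2's would otherwise dominate).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LipidTemplate:
    """Bead-level description of one coarse-grained lipid species.

    Parameters
    ----------
    species_name:
        Residue name used in coordinate files (e.g. ``"SDPC"``).
    phosphate_bead:
        Reference bead used for leaflet clustering and zone assignment.
        For sterols this is the hydroxyl-equivalent anchor bead.
    headgroup_beads:
        Beads belonging to the polar headgroup (excluded from composition
        counting).  Empty for sterols.
    headgroup_reference_bead:
        Single bead whose (theta, z) position enters the 2D headgroup
        surface-density maps (NC3 for SDPC, CNO for POPS, C1 for PIP2).
        ``None`` for species that do not contribute to headgroup maps.
    tail_terminal_beads:
        Last bead of each acyl tail, ordered (sn-1, sn-2).  Empty for
        sterols; a species with at least one entry is treated as a
        phospholipid.
    glycerol_beads:
        Glycerol-backbone beads (used for leaflet-thickness planes).
    nonheadgroup_bead_count:
        Number of beads of a whole molecule excluding the headgroup; the
        molar-composition divisor.
    br_atoms_per_molecule:
        Bromine atoms carried by the fully brominated analog of this
        species (2 per double bond).
    """

    species_name: str
    phosphate_bead: str
    headgroup_beads: frozenset[str] = field(default_factory=frozenset)
    headgroup_reference_bead: str | None = None
    tail_terminal_beads: tuple[str, ...] = ()
    glycerol_beads: frozenset[str] = field(default_factory=frozenset)
    nonheadgroup_bead_count: int = 1
    br_atoms_per_molecule: float = 0.0

    def __post_init__(self) -> None:
        if self.nonheadgroup_bead_count < 1:
            raise ValueError(
                f"{self.species_name}: nonheadgroup_bead_count must be >= 1"
            )
        if self.br_atoms_per_molecule < 0:
            raise ValueError(f"{self.species_name}: br_atoms_per_molecule < 0")

    @property
    def is_sterol(self) -> bool:
        """Sterols carry no acyl tails (and no multi-bead headgroup)."""
        return len(self.tail_terminal_beads) == 0

    @property
    def all_beads(self) -> frozenset[str]:
        return frozenset(self.headgroup_beads) | frozenset(self.bead_order())

    def bead_order(self) -> tuple[str, ...]:
        """Canonical bead ordering used by the synthetic generator."""
        return tuple(_BEAD_ORDERS[self.species_name])

    def nonheadgroup_beads(self) -> frozenset[str]:
        return frozenset(b for b in self.bead_order() if b not in self.headgroup_beads)

    def tail_beads(self) -> tuple[tuple[str, ...], ...]:
        """Bead labels of each acyl tail, ordered from glycerol to terminus."""
        tails = []
        for terminal in self.tail_terminal_beads:
            suffix = terminal[-1]
            tail = tuple(
                b for b in self.bead_order()
                if b.endswith(suffix)
                and b not in self.headgroup_beads
                and b not in self.glycerol_beads
                and b != self.phosphate_bead
            )
            if not tail or tail[-1] != terminal:
                raise ValueError(
                    f"{self.species_name}: cannot resolve tail ending at {terminal}")
            tails.append(tail)
        return tuple(tails)


# Bead layouts follow the Martini 2.2 lipid models used for the tubule system:
# SDPC (Martini PUPC, 18:0/22:6 PC), POPS, CHOL and a di-oleoyl PIP2.
_BEAD_ORDERS: dict[str, tuple[str, ...]] = {
    "SDPC": (
        "NC3", "PO4", "GL1", "GL2",
        "C1A", "C2A", "C3A", "C4A",            # sn-1 stearoyl
        "D1B", "D2B", "D3B", "D4B", "D5B",     # sn-2 docosahexaenoyl
    ),
    "POPS": (
        "CNO", "PO4", "GL1", "GL2",
        "C1A", "C2A", "C3A", "C4A",            # sn-1 palmitoyl
        "C1B", "D2B", "C3B", "C4B",            # sn-2 oleoyl
    ),
    "CHOL": ("ROH", "R1", "R2", "R3", "R4", "R5", "C1", "C2"),
    "PIP2": (
        "C1", "C2", "C3", "P4", "P5",          # inositol-bisphosphate headgroup
        "PO4", "GL1", "GL2",
        "C1A", "D2A", "C3A", "C4A",            # sn-1 oleoyl
        "C1B", "D2B", "C3B", "C4B",            # sn-2 oleoyl
    ),
}

#: Default templates for the four-species tubule mixture.  Non-headgroup
#: bead counts: SDPC 12, POPS 11, CHOL 8, PIP2 11; PIP2 carries a 5-bead
#: headgroup while SDPC and POPS carry 1.
DEFAULT_TEMPLATES: dict[str, LipidTemplate] = {
    "SDPC": LipidTemplate(
        species_name="SDPC",
        phosphate_bead="PO4",
        headgroup_beads=frozenset({"NC3"}),
        headgroup_reference_bead="NC3",
        tail_terminal_beads=("C4A", "D5B"),
        glycerol_beads=frozenset({"GL1", "GL2"}),
        nonheadgroup_bead_count=12,
        br_atoms_per_molecule=12.0,   # 6 double bonds on the 22:6 tail
    ),
    "POPS": LipidTemplate(
        species_name="POPS",
        phosphate_bead="PO4",
        headgroup_beads=frozenset({"CNO"}),
        headgroup_reference_bead="CNO",
        tail_terminal_beads=("C4A", "C4B"),
        glycerol_beads=frozenset({"GL1", "GL2"}),
        nonheadgroup_bead_count=11,
        br_atoms_per_molecule=2.0,
    ),
    "CHOL": LipidTemplate(
        species_name="CHOL",
        phosphate_bead="ROH",
        headgroup_beads=frozenset(),
        headgroup_reference_bead=None,
        tail_terminal_beads=(),
        glycerol_beads=frozenset(),
        nonheadgroup_bead_count=8,
        br_atoms_per_molecule=2.0,
    ),
    "PIP2": LipidTemplate(
        species_name="PIP2",
        phosphate_bead="PO4",
        headgroup_beads=frozenset({"C1", "C2", "C3", "P4", "P5"}),
        headgroup_reference_bead="C1",
        tail_terminal_beads=("C4A", "C4B"),
        glycerol_beads=frozenset({"GL1", "GL2"}),
        nonheadgroup_bead_count=11,
        br_atoms_per_molecule=4.0,
    ),
}
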