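"""Inter-subunit contact detection and surface classification.

Spiral nitrilase oligomers bury several distinct interfaces: the A-surface
joins two monomers into the dimer building block, the C-surface joins
consecutive dimers along the spiral, and cross-groove contacts between
adjacent turns (the D- and E-surfaces of the EM literature) stabilise or
terminate the spiral.  D and E are distinguished experimentally by outcome,
not geometry, so both map to a single ``CROSS_GROOVE`` label here.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .helix import AssemblyModel, ScrewParameters

__all__ = [
    "Contact",
    "SurfaceLabel",
    "RegionDefinition",
    "RegionSummary",
    "RegionReport",
    "find_contacts",
    "classify_surface_pairs",
    "region_interface_report",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_GROOVE_TOLERANCE",
    "DEFAULT_REGIONS",
]

#: heavy-atom contact cutoff in Angstrom (common structural-biology convention)
DEFAULT_CONTACT_CUTOFF = 4.5
#: how close (deg) a cumulative-rotation difference must be to 360 deg to call
#: a pair cross-groove
DEFAULT_GROOVE_TOLERANCE = 30.0


class SurfaceLabel(str, enum.Enum):
    A = "A"
    C = "C"
    CROSS_GROOVE = "cross_groove"
    NONE = "none"


@dataclasses.dataclass(frozen=True)
class Contact:
    """One inter-copy heavy-atom contact, canonically ordered copy_i < copy_j."""

    copy_i: int
    copy_j: int
    residue_i: tuple[str, int]  # (chain, residue number)
    residue_j: tuple[str, int]
    atom_i: str
    atom_j: str
    distance: float  # Angstrom


@dataclasses.dataclass(frozen=True)
class RegionDefinition:
    """A named residue range, 1-based and inclusive at both ends."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end


#: the two C-surface insertion regions of B. pumilus CynD
DEFAULT_REGIONS = (
    RegionDefinition("region1", 55, 72),
    RegionDefinition("region2", 222, 235),
)


def find_contacts(assembly: AssemblyModel, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> list[Contact]:
    """All heavy-atom pairs from distinct copies within ``cutoff`` Angstrom.

    Hydrogens and HETATM records are excluded.  Output is deterministic,
    sorted by (copy_i, copy_j, distance).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if assembly.n_copies < 2:
        raise ValueError("contacts need an assembly with at least 2 copies")
    positions = []
    meta = []  # (copy, chain, resnum, atom_name)
    for copy in assembly.copies:
        for a in copy.model.atoms:
            if a.het or a.element.upper() == "H":
                continue
            positions.append(a.position)
            meta.append((copy.copy_index, a.chain_id, a.residue_number, a.atom_name))
    pts = np.asarray(positions)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    contacts = []
    for i, j in pairs:
        mi, mj = meta[i], meta[j]
        if mi[0] == mj[0]:
            continue
        if mi[0] > mj[0]:
            mi, mj, i, j = mj, mi, j, i
        d = float(np.linalg.norm(pts[i] - pts[j]))
        contacts.append(
            Contact(
                copy_i=mi[0],
                copy_j=mj[0],
                residue_i=(mi[1], mi[2]),
                residue_j=(mj[1], mj[2]),
                atom_i=mi[3],
                atom_j=mj[3],
                distance=d,
            )
        )
    contacts.sort(key=lambda c: (c.copy_i, c.copy_j, c.distance, c.residue_i, c.residue_j))
    return contacts


def classify_surface_pairs(
    assembly: AssemblyModel,
    screw: Optional[ScrewParameters] = None,
    groove_tolerance_deg: float = DEFAULT_GROOVE_TOLERANCE,
    dimer_pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> dict[tuple[int, int], SurfaceLabel]:
    """Label every copy pair with the interface it can form.

    * pairs inside one declared dimer (``dimer_pairs``, for monomer-unit
      assemblies) -> ``A``;
    * consecutive copies -> ``C`` (the spiral-elongation surface);
    * pairs whose cumulative rotation differs by ~360 deg (within
      ``groove_tolerance_deg``) -> ``CROSS_GROOVE`` (D/E candidates);
    * everything else -> ``NONE``.
    """
    screw = screw or assembly.screw
    if screw is None:
        raise ValueError("assembly has no screw metadata; pass screw explicitly")
    declared = {tuple(sorted(p)) for p in (dimer_pairs or [])}
    labels: dict[tuple[int, int], SurfaceLabel] = {}
    n = assembly.n_copies
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in declared:
                labels[(i, j)] = SurfaceLabel.A
            elif j - i == 1:
                labels[(i, j)] = SurfaceLabel.C
            else:
                dphi = abs((j - i) * screw.signed_twist_deg)
                if abs(dphi - 360.0) <= groove_tolerance_deg:
                    labels[(i, j)] = SurfaceLabel.CROSS_GROOVE
                else:
                    labels[(i, j)] = SurfaceLabel.NONE
    return labels


@dataclasses.dataclass
class RegionSummary:
    region: RegionDefinition
    interface_residues: list[int]  # distinct residue numbers with >= 1 contact
    contact_fraction: float  # fraction of considered contacts touching the region


@dataclasses.dataclass
class RegionReport:
    per_region: dict[str, RegionSummary]
    residues_outside_regions: list[int]
    per_residue_contacts: dict[int, int]  # residue number -> contact count
    empty_warning: bool


def region_interface_report(
    contacts: Sequence[Contact],
    regions: Sequence[RegionDefinition] = DEFAULT_REGIONS,
    restrict_label: Optional[SurfaceLabel] = None,
    labels: Optional[dict[tuple[int, int], SurfaceLabel]] = None,
) -> RegionReport:
    """Summarise how interface residues distribute over sequence regions.

    A residue is an interface residue if it participates in at least one
    atomic contact.  When ``restrict_label`` and ``labels`` are given, only
    contacts between copy pairs carrying that label are considered (e.g. the
    C-surface).  The per-residue contact-count table is the mutagenesis
    target list: every residue worth probing, with how often it touches a
    neighbouring copy.
    """
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if regions[a].start <= regions[b].end and regions[b].start <= regions[a].end:
                raise ValueError(f"regions {regions[a].name} and {regions[b].name} overlap")
    if restrict_label is not None:
        if labels is None:
            raise ValueError("restrict_label requires the surface label map")
        contacts = [
            c for c in contacts if labels.get((c.copy_i, c.copy_j)) == restrict_label
        ]
    per_residue: dict[int, int] = {}
    for c in contacts:
        for (_, resnum) in (c.residue_i, c.residue_j):
            per_residue[resnum] = per_residue.get(resnum, 0) + 1
    total = len(contacts)
    per_region: dict[str, RegionSummary] = {}
    for region in regions:
        in_region = sorted(r for r in per_residue if r in region)
        touching = sum(
            1
            for c in contacts
            if c.residue_i[1] in region or c.residue_j[1] in region
        )
        per_region[region.name] = RegionSummary(
            region=region,
            interface_residues=in_region,
            contact_fraction=(touching / total) if total else 0.0,
        )
    outside = sorted(
        r for r in per_residue if not any(r in region for region in regions)
    )
    return RegionReport(
        per_region=per_region,
        residues_outside_regions=outside,
        per_residue_contacts=dict(sorted(per_residue.items())),
        empty_warning=(total == 0),
    )
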