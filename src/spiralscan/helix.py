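"""Screw-axis geometry: building spiral assemblies and recovering their parameters.

Spiral nitrilases such as CynD grow by repeating a dimer building block along
a screw axis: each step rotates by a fixed twist about the axis and translates
by a fixed rise along it.  CynD's extended helices have a rise of 1.62 nm and
a left-handed twist of 77 deg per dimer; related enzymes differ (beta-alanine
synthase 1.41 nm / 83.1 deg left; the *Synechocystis* oxy-nitrilase
2.68 nm / 60.0 deg left, i.e. exact sixfold symmetry).

Conventions
-----------
* The screw axis is the +z axis through the origin; callers pre-orient
  structures (the synthetic generators emit them pre-oriented).
* Left-handed means a negative rotation about +z per positive rise; twist is
  always reported as a magnitude plus a handedness flag.
* User-facing lengths (rise, diameters) are nm; coordinates are Angstrom.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import StructureModel, CHAIN_ALPHABET, StructureError

__all__ = [
    "Handedness",
    "ScrewParameters",
    "AssemblyCopy",
    "AssemblyModel",
    "SuperpositionResult",
    "ScrewEstimate",
    "DegenerateScrewError",
    "NotHelicalError",
    "superpose",
    "build_helical_assembly",
    "estimate_screw_parameters",
    "dimers_per_turn",
    "outer_diameter",
    "assembly_to_model",
    "CYND_SCREW",
    "BAS_SCREW",
    "OXYNITRILASE_SCREW",
    "NM_PER_ANGSTROM",
]

NM_PER_ANGSTROM = 0.1


class Handedness(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class DegenerateScrewError(ValueError):
    """Consecutive copies related by (near-)identity: no screw to estimate."""


class NotHelicalError(ValueError):
    """Pairwise transforms disagree beyond tolerance: not a single-screw helix."""


@dataclasses.dataclass(frozen=True)
class ScrewParameters:
    """Per-step helical rise (nm), twist magnitude (deg) and handedness."""

    rise_nm: float
    twist_deg: float
    handedness: Handedness = Handedness.LEFT

    def __post_init__(self) -> None:
        if not self.rise_nm > 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist_deg < 360:
            raise ValueError("twist must lie in (0, 360) degrees")
        object.__setattr__(self, "handedness", Handedness(self.handedness))

    @property
    def signed_twist_deg(self) -> float:
        """Signed rotation about +z per step: negative for left-handed."""
        return -self.twist_deg if self.handedness is Handedness.LEFT else self.twist_deg

    @property
    def rise_angstrom(self) -> float:
        return self.rise_nm / NM_PER_ANGSTROM


#: CynD extended-helix parameters (per dimer step).
CYND_SCREW = ScrewParameters(rise_nm=1.62, twist_deg=77.0, handedness=Handedness.LEFT)
#: *D. melanogaster* beta-alanine synthase crystal spiral.
BAS_SCREW = ScrewParameters(rise_nm=1.41, twist_deg=83.1, handedness=Handedness.LEFT)
#: *Synechocystis* oxy-nitrilase crystal helix (sixfold symmetric).
OXYNITRILASE_SCREW = ScrewParameters(rise_nm=2.68, twist_deg=60.0, handedness=Handedness.LEFT)


@dataclasses.dataclass
class AssemblyCopy:
    copy_index: int
    model: StructureModel
    cumulative_rotation_deg: float  # signed, about +z
    cumulative_rise_nm: float


@dataclasses.dataclass
class AssemblyModel:
    """Ordered protomer copies with per-copy cumulative screw metadata."""

    copies: list[AssemblyCopy]
    source: StructureModel
    screw: Optional[ScrewParameters] = None

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def coords(self, copy_index: int) -> np.ndarray:
        return self.copies[copy_index].model.coords


@dataclasses.dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclasses.dataclass
class ScrewEstimate:
    """Estimated screw parameters plus per-pair consistency diagnostics."""

    parameters: ScrewParameters
    twist_spread_deg: float
    rise_spread_nm: float
    axis_spread_deg: float
    n_pairs: int
    mean_axis: np.ndarray

    @property
    def rise_nm(self) -> float:
        return self.parameters.rise_nm

    @property
    def twist_deg(self) -> float:
        return self.parameters.twist_deg

    @property
    def handedness(self) -> Handedness:
        return self.parameters.handedness


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation + translation superposition (Kabsch).

    The two point sets are paired index-wise.  Reflections are excluded by
    construction, so a mirrored input yields the best proper rotation with a
    nonzero RMSD rather than a determinant of -1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    mob_c = mobile - mc
    ref_c = reference - rc
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = rc - R @ mc
    diff = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _screw_matrix(signed_twist_deg: float, rise_angstrom: float) -> tuple[np.ndarray, np.ndarray]:
    theta = math.radians(signed_twist_deg)
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([0.0, 0.0, rise_angstrom])
    return R, t


def build_helical_assembly(
    protomer: StructureModel, screw: ScrewParameters, n_copies: int
) -> AssemblyModel:
    """Place ``n_copies`` copies of a protomer along the screw.

    Copy *k* has coordinates ``Rz(k * theta) x + k * (0, 0, rise)`` with theta
    the signed twist.  The protomer must already sit at its intended radius
    from the z-axis; the builder applies the screw verbatim and never
    re-centres.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    protomer.validate()
    R, t = _screw_matrix(screw.signed_twist_deg, screw.rise_angstrom)
    coords = protomer.coords
    copies = []
    cur = coords
    for k in range(n_copies):
        if k > 0:
            cur = cur @ R.T + t
        copies.append(
            AssemblyCopy(
                copy_index=k,
                model=protomer.with_coords(cur, label=f"{protomer.label}|copy{k}"),
                cumulative_rotation_deg=k * screw.signed_twist_deg,
                cumulative_rise_nm=k * screw.rise_nm,
            )
        )
    return AssemblyModel(copies=copies, source=protomer, screw=screw)


def estimate_screw_parameters(
    assembly: AssemblyModel,
    axis_tolerance_deg: float = 1.0,
    rise_tolerance_frac: float = 0.01,
) -> ScrewEstimate:
    """Recover rise/twist/handedness from consecutive-copy rigid transforms.

    Each consecutive copy pair is superposed to get its relative rigid
    transform, which is decomposed into axis-angle form; the axis is oriented
    so the rise is positive, the twist is the angle magnitude, and the
    handedness is the sign of the rotation about the rise-positive axis.
    Estimates are averaged over pairs; the spreads are returned as a
    consistency diagnostic and gate the "not helical" error.
    """
    if assembly.n_copies < 2:
        raise ValueError("need at least 2 copies to estimate a screw")
    axes = []
    rises = []
    twists = []
    signs = []
    for k in range(assembly.n_copies - 1):
        a = assembly.coords(k)
        b = assembly.coords(k + 1)
        if a.shape[0] < 3:
            raise ValueError("need at least 3 atoms per copy")
        sup = superpose(a, b)
        rotvec = Rotation.from_matrix(sup.rotation).as_rotvec()
        angle = float(np.linalg.norm(rotvec))
        if math.degrees(angle) < 1e-6:
            raise DegenerateScrewError(
                "consecutive copies related by (near-)identity: no screw"
            )
        axis = rotvec / angle
        rise_a = float(sup.translation @ axis)
        sign = 1.0
        if rise_a < 0:
            axis = -axis
            rise_a = -rise_a
            sign = -1.0
        axes.append(axis)
        rises.append(rise_a)
        twists.append(math.degrees(angle))
        signs.append(sign)
    axes_arr = np.asarray(axes)
    mean_axis = axes_arr.mean(axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    cosines = np.clip(axes_arr @ mean_axis, -1.0, 1.0)
    axis_spread = float(np.degrees(np.max(np.arccos(cosines))))
    mean_rise_a = float(np.mean(rises))
    rise_spread_a = float(np.max(np.abs(np.asarray(rises) - mean_rise_a)))
    mean_twist = float(np.mean(twists))
    twist_spread = float(np.max(np.abs(np.asarray(twists) - mean_twist)))
    if axis_spread > axis_tolerance_deg or rise_spread_a > rise_tolerance_frac * mean_rise_a:
        raise NotHelicalError(
            f"pairwise transforms inconsistent (axis spread {axis_spread:.3g} deg, "
            f"rise spread {rise_spread_a:.3g} A): not a single-screw helix"
        )
    if len(set(signs)) > 1:
        raise NotHelicalError("handedness flips between consecutive pairs")
    handed = Handedness.LEFT if signs[0] < 0 else Handedness.RIGHT
    params = ScrewParameters(
        rise_nm=mean_rise_a * NM_PER_ANGSTROM,
        twist_deg=mean_twist,
        handedness=handed,
    )
    return ScrewEstimate(
        parameters=params,
        twist_spread_deg=twist_spread,
        rise_spread_nm=rise_spread_a * NM_PER_ANGSTROM,
        axis_spread_deg=axis_spread,
        n_pairs=len(rises),
        mean_axis=mean_axis,
    )


def dimers_per_turn(screw: ScrewParameters) -> float:
    """Dimer steps per full 360 deg turn of the spiral (360 / twist)."""
    return 360.0 / screw.twist_deg


def outer_diameter(assembly: AssemblyModel) -> float:
    """Outer diameter of the assembly in nm: twice the maximum radial distance
    of any atom from the z-axis.  A screw about z preserves radii, so this
    equals the source protomer's maximal radius doubled."""
    if assembly.n_copies == 0:
        raise ValueError("empty assembly")
    max_r = 0.0
    for copy in assembly.copies:
        xy = copy.model.coords[:, :2]
        r = float(np.sqrt((xy**2).sum(axis=1)).max()) if len(xy) else 0.0
        max_r = max(max_r, r)
    return 2.0 * max_r * NM_PER_ANGSTROM


def assembly_to_model(assembly: AssemblyModel) -> StructureModel:
    """Flatten an assembly to one model, remapping chains deterministically.

    Copy k's chains are relabelled in order A, B, C, ... through the 62-symbol
    alphabet (upper, lower, digits); more chains than that cannot be written
    to single-column PDB chain IDs and raise an error.
    """
    n_chains_per_copy = len(assembly.source.chain_ids)
    total = n_chains_per_copy * assembly.n_copies
    if total > len(CHAIN_ALPHABET):
        raise StructureError(
            f"{total} chains exceed the {len(CHAIN_ALPHABET)} single-character "
            "PDB chain IDs available"
        )
    atoms = []
    idx = 0
    for copy in assembly.copies:
        local = {c: CHAIN_ALPHABET[idx + i] for i, c in enumerate(copy.model.chain_ids)}
        idx += n_chains_per_copy
        for a in copy.model.atoms:
            na = a.copy()
            na.chain_id = local[a.chain_id]
            atoms.append(na)
    return StructureModel(atoms, label=f"{assembly.source.label}|assembly")
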