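"""Synthetic-data generators with known ground truth for every pipeline stage.

Everything downstream of raw data can be exercised without downloads: toy
protomers and C2 dimers with engineered interface contacts, noisy spiral
assemblies, SEC chromatograms drawn on a known calibration line, alignments
with planted insertions, and endpoint assay plates with known true
activities.  All generators are seed-deterministic and return a
machine-readable truth record alongside their output.

The fixtures are coarse-grained pseudo-structures, not physical protein
models: a Calpha lattice carries the geometry and interface residues carry a
single protruding pseudo-sidechain atom aimed at where the next screw copy
will sit, which guarantees (and confines) inter-copy contacts at the planted
residues.
"""

from __future__ import annotations

import dataclasses
import math
import string
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignments import Alignment
from .helix import (
    AssemblyModel,
    CYND_SCREW,
    ScrewParameters,
    build_helical_assembly,
)
from .sec import CalibrationFit, Chromatogram, SIGMA_STANDARD_MASSES_DA, CalibrationStandard
from .structure import AtomRecord, StructureModel

__all__ = [
    "make_toy_protomer",
    "make_c2_dimer",
    "simulate_assembly",
    "simulate_chromatogram",
    "simulate_assay_plate",
    "simulate_alignment",
    "cynd_like_alignment",
    "truth_calibration",
    "truth_standards",
    "elution_volume_for_mass",
    "TRUTH_CALIBRATION_SLOPE",
    "TRUTH_CALIBRATION_INTERCEPT",
    "TRUTH_V0_ML",
    "TRUTH_VT_ML",
    "DEFAULT_PROTOMER_RADIUS_A",
    "DEFAULT_N_DIMERS",
]

# --- truth constants shared by the SEC generators ------------------------
# A 10/300-format column: void 8 ml, total 24 ml; log10(mass/Da) = 6 - 2.3*Kav
# puts the exclusion limit at 1 MDa and the six marker masses comfortably
# inside the separating range.
TRUTH_V0_ML = 8.0
TRUTH_VT_ML = 24.0
TRUTH_CALIBRATION_SLOPE = -2.3
TRUTH_CALIBRATION_INTERCEPT = 6.0

#: radius (Angstrom) placing the farthest protomer atom so the assembly's
#: outer diameter matches the 11 nm seen for CynD helices in micrographs
DEFAULT_PROTOMER_RADIUS_A = 55.0
#: a self-terminating CynD spiral is an 18-mer: nine dimers
DEFAULT_N_DIMERS = 9

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# lattice constants for the toy protomer (Angstrom); see docs/methods.md
_LATTICE_SPACING = 5.5
_BASE_Z = 5.0
_CB_OFFSET = 3.0


def _hex_grid(max_radius: float, spacing: float) -> np.ndarray:
    """Hexagonal 2-D lattice points within a disc, sorted by radius."""
    dx = spacing
    dy = spacing * math.sqrt(3) / 2
    n = int(max_radius / dy) + 2
    pts = []
    for row in range(-n, n + 1):
        y = row * dy
        off = (row % 2) * dx / 2
        m = int(max_radius / dx) + 2
        for col in range(-m, m + 1):
            x = col * dx + off
            if x * x + y * y <= max_radius * max_radius:
                pts.append((x, y))
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p[1], p[0]))
    return np.asarray(pts)


def _screw_apply(p: np.ndarray, screw: ScrewParameters) -> np.ndarray:
    theta = math.radians(screw.signed_twist_deg)
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return p @ R.T + np.array([0.0, 0.0, screw.rise_angstrom])


def make_toy_protomer(
    n_residues: int = 330,
    radius: float = DEFAULT_PROTOMER_RADIUS_A,
    interface_residues: Iterable[int] = (),
    seed: int = 0,
    screw: ScrewParameters = CYND_SCREW,
    jitter_sd: float = 0.05,
    chain_id: str = "A",
    sequence: Optional[str] = None,
) -> StructureModel:
    """A coarse-grained single-chain protomer pre-oriented on the z-axis.

    Calpha pseudo-atoms occupy one hexagonal lattice layer (5.5 A spacing)
    at z = +5 A, so a C2 dimer (mate at z = -5 A) stays well inside one
    1.62 nm screw step; the farthest atom sits exactly at ``radius`` from the
    axis.  Residues in ``interface_residues`` get one extra pseudo-sidechain
    atom ("CB") placed 3 A short (along -z) of where that residue's image
    under ``screw`` will sit, so consecutive screw copies form contacts at
    exactly those residues and nowhere else (at the conventional 4.5 A
    heavy-atom cutoff).
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    interface = sorted(set(interface_residues))
    if interface and (interface[0] < 1 or interface[-1] > n_residues):
        raise ValueError("interface residues outside 1..n_residues")
    grid = _hex_grid(radius, _LATTICE_SPACING)
    if len(grid) < n_residues:
        raise ValueError(
            f"radius {radius} A too small to place {n_residues} residues at "
            f"{_LATTICE_SPACING} A lattice spacing"
        )
    rng = np.random.default_rng(seed)
    ca = np.column_stack(
        [grid[:n_residues, 0], grid[:n_residues, 1], np.full(n_residues, _BASE_Z)]
    )
    if jitter_sd > 0:
        ca += rng.normal(0.0, jitter_sd, ca.shape)
    # rescale xy so the farthest Calpha sits exactly at the stated radius
    r = np.sqrt((ca[:, :2] ** 2).sum(axis=1))
    rmax = r.max()
    if rmax > 0:
        ca[:, :2] *= radius / rmax
    seq = sequence or "".join(rng.choice(list(_AA), size=n_residues))
    if len(seq) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    atoms = []
    for i in range(n_residues):
        resnum = i + 1
        resname = _AA3.get(seq[i].upper(), "GLY")
        atoms.append(
            AtomRecord(chain_id, resnum, resname, "CA", "C", ca[i].copy())
        )
        if resnum in set(interface):
            # protrude toward the next copy's site: 3 A short of this
            # residue's image under the screw, offset along -z so that the
            # only atom within the 4.5 A cutoff is the partner Calpha
            image = _screw_apply(ca[i], screw)
            cb = image - np.array([0.0, 0.0, _CB_OFFSET])
            atoms.append(AtomRecord(chain_id, resnum, resname, "CB", "C", cb))
    model = StructureModel(atoms, label=f"toy_protomer_n{n_residues}")
    model.validate()
    return model


def make_c2_dimer(
    protomer: StructureModel,
    dyad_axis: Sequence[float] = (1.0, 0.0, 0.0),
    chain_ids: tuple[str, str] = ("A", "B"),
    clash_cutoff: float = 2.0,
) -> StructureModel:
    """Join a protomer and its 180-deg rotation about the dyad into a dimer.

    The dyad axis passes through the origin; with the default x-axis dyad a
    protomer occupying z > 0 maps to z < 0 and the two chains cannot clash.
    The clash count (atom pairs closer than ``clash_cutoff``) is required to
    be zero.
    """
    axis = np.asarray(dyad_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("dyad axis must be a unit vector")
    # Rodrigues formula at 180 deg: R = 2 a a^T - I
    R = 2.0 * np.outer(axis, axis) - np.eye(3)
    coords_a = protomer.coords
    coords_b = coords_a @ R.T
    from scipy.spatial import cKDTree

    n_clash = cKDTree(coords_a).query_ball_tree(cKDTree(coords_b), r=clash_cutoff)
    clashes = sum(len(hits) for hits in n_clash)
    if clashes:
        raise ValueError(f"C2 placement clashes: {clashes} atom pairs < {clash_cutoff} A")
    atoms = []
    for a, pos in zip(protomer.atoms, coords_a):
        na = a.copy()
        na.chain_id = chain_ids[0]
        atoms.append(na)
    for a, pos in zip(protomer.atoms, coords_b):
        na = a.copy()
        na.chain_id = chain_ids[1]
        na.position = pos.copy()
        atoms.append(na)
    return StructureModel(atoms, label=f"{protomer.label}|c2dimer")


@dataclasses.dataclass
class AssemblyTruth:
    screw: ScrewParameters
    n_copies: int
    noise_sd: float
    seed: int
    interface_residues: list[int]


def simulate_assembly(
    protomer: StructureModel,
    screw: ScrewParameters = CYND_SCREW,
    n_copies: int = DEFAULT_N_DIMERS,
    noise_sd: float = 0.0,
    seed: int = 0,
    interface_residues: Iterable[int] = (),
) -> tuple[AssemblyModel, AssemblyTruth]:
    """Build a screw assembly and optionally perturb it with isotropic noise.

    The default reproduces the self-terminating CynD spiral: nine dimer
    copies on the 1.62 nm / 77 deg left-handed screw.
    """
    if n_copies < 2:
        raise ValueError("need at least 2 copies for downstream screw estimation")
    assembly = build_helical_assembly(protomer, screw, n_copies)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for copy in assembly.copies:
            noisy = copy.model.coords + rng.normal(0.0, noise_sd, (len(copy.model), 3))
            copy.model = copy.model.with_coords(noisy, label=copy.model.label)
    truth = AssemblyTruth(
        screw=screw,
        n_copies=n_copies,
        noise_sd=noise_sd,
        seed=seed,
        interface_residues=sorted(set(interface_residues)),
    )
    return assembly, truth


# --- SEC ------------------------------------------------------------------

def truth_calibration() -> CalibrationFit:
    """The generator's ground-truth calibration line as a CalibrationFit."""
    return CalibrationFit(
        mode="kav",
        v0_ml=TRUTH_V0_ML,
        vt_ml=TRUTH_VT_ML,
        slope=TRUTH_CALIBRATION_SLOPE,
        intercept=TRUTH_CALIBRATION_INTERCEPT,
        r_squared=1.0,
        x_min=0.0,
        x_max=1.0,
    )


def elution_volume_for_mass(mass_kda: float) -> float:
    """Elution volume implied by the truth line; masses above the exclusion
    limit (1 MDa) elute in the void."""
    log_mass = math.log10(mass_kda * 1000.0)
    kav = (log_mass - TRUTH_CALIBRATION_INTERCEPT) / TRUTH_CALIBRATION_SLOPE
    if kav <= 0:
        return TRUTH_V0_ML
    return TRUTH_V0_ML + kav * (TRUTH_VT_ML - TRUTH_V0_ML)


def truth_standards() -> list[CalibrationStandard]:
    """The six marker proteins placed exactly on the truth line."""
    return [
        CalibrationStandard(name, float(mass), elution_volume_for_mass(mass / 1000.0))
        for name, mass in SIGMA_STANDARD_MASSES_DA.items()
    ]


@dataclasses.dataclass
class ChromatogramTruth:
    composition: list[tuple[int, float]]  # (n_mer, normalized weight)
    species_volumes_ml: list[float]
    monomer_mass_kda: float
    peak_sd_ml: float
    noise_sd_au: float
    seed: int


def simulate_chromatogram(
    composition: Sequence[tuple[int, float]],
    monomer_mass_kda: float = 37.0,
    peak_sd_ml: float = 0.15,
    noise_sd_au: float = 0.002,
    seed: int = 0,
    wavelength_nm: int = 220,
) -> tuple[Chromatogram, ChromatogramTruth]:
    """A Gaussian-mixture chromatogram on the truth calibration line.

    Each (n_mer, weight) species becomes a Gaussian of area proportional to
    its weight, centred at the elution volume its mass implies; species above
    the exclusion limit pile up at the void volume.  The grid is 0.02 ml
    steps over 7-25 ml, mimicking a 10/300-format run.
    """
    if not composition:
        raise ValueError("empty composition")
    weights = np.array([w for _, w in composition], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("species weights must be positive")
    weights = weights / weights.sum()
    volumes = [elution_volume_for_mass(n * monomer_mass_kda) for n, _ in composition]
    grid = np.arange(7.0, 25.0 + 1e-9, 0.02)
    trace = np.zeros_like(grid)
    for vol, w in zip(volumes, weights):
        trace += w / (peak_sd_ml * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((grid - vol) / peak_sd_ml) ** 2
        )
    rng = np.random.default_rng(seed)
    if noise_sd_au > 0:
        trace = trace + rng.normal(0.0, noise_sd_au, trace.shape)
    trace = np.clip(trace, 0.0, None)
    chrom = Chromatogram(grid, trace, wavelength_nm)
    truth = ChromatogramTruth(
        composition=[(n, float(w)) for (n, _), w in zip(composition, weights)],
        species_volumes_ml=volumes,
        monomer_mass_kda=monomer_mass_kda,
        peak_sd_ml=peak_sd_ml,
        noise_sd_au=noise_sd_au,
        seed=seed,
    )
    return chrom, truth


# --- assay plates ---------------------------------------------------------

@dataclasses.dataclass
class PlateTruth:
    true_pct: dict[str, float]
    wt_a520: float
    blank_a520: float
    cv: float
    replicates: int
    seed: int


def simulate_assay_plate(
    true_pct: Mapping[str, float],
    wt_blank_a520: tuple[float, float] = (0.15, 1.10),
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlateTruth]:
    """Endpoint picric-acid plate readings with known true activities.

    Sample means are interpolated between the blank (0%) and wild-type
    (100%) anchors; multiplicative Gaussian noise with the stated CV is
    applied per replicate.  Returns rows sample_id,replicate,a520 including
    'wt' and 'blank' wells.
    """
    wt_a, blank_a = wt_blank_a520
    if blank_a <= wt_a:
        raise ValueError("blank A520 must exceed wild-type A520")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample_id: str, mean: float) -> None:
        for rep in range(1, replicates + 1):
            val = mean * (1.0 + rng.normal(0.0, cv))
            rows.append((sample_id, rep, max(val, 0.0)))

    emit("blank", blank_a)
    emit("wt", wt_a)
    for mutant, pct in true_pct.items():
        mean = blank_a - (pct / 100.0) * (blank_a - wt_a)
        emit(mutant, mean)
    df = pd.DataFrame(rows, columns=["sample_id", "replicate", "a520"])
    truth = PlateTruth(
        true_pct=dict(true_pct),
        wt_a520=wt_a,
        blank_a520=blank_a,
        cv=cv,
        replicates=replicates,
        seed=seed,
    )
    return df, truth


# --- alignments -----------------------------------------------------------

@dataclasses.dataclass
class AlignmentTruth:
    insertions: list[tuple[int, int, tuple[str, ...]]]  # (core pos, length, members)
    member_lengths: dict[tuple[int, str], int]
    query_regions: dict[str, list[tuple[int, int]]]  # member -> [(start, end)] 1-based


def simulate_alignment(
    core_length: int,
    insertions: Sequence[tuple[int, int, Sequence[str]]],
    spiral_ids: Sequence[str],
    reference_ids: Sequence[str],
    seed: int = 0,
    member_lengths: Optional[Mapping[tuple[int, str], int]] = None,
) -> tuple[Alignment, AlignmentTruth]:
    """An alignment with insertions planted at known core positions.

    ``insertions`` are (core_position, length, member_ids): after
    ``core_position`` core residues, ``length`` columns are inserted in which
    only the named members carry residues; everyone else (including all
    ``reference_ids``) is gapped.  ``member_lengths[(k, member)]`` shortens
    insertion ``k`` for one member (e.g. a region eight residues shorter in a
    homolog); the shorter run is left-justified in the block.
    """
    if core_length < 1:
        raise ValueError("core_length must be positive")
    order = sorted(insertions, key=lambda ins: ins[0])
    positions = [p for p, _, _ in order]
    for (p1, l1, _), (p2, _, _) in zip(order[:-1], order[1:]):
        if p1 == p2:
            raise ValueError("overlapping insertions (same core position)")
    if positions and (positions[0] < 0 or positions[-1] > core_length):
        raise ValueError("insertion positions must lie within the core")
    member_lengths = dict(member_lengths or {})
    rng = np.random.default_rng(seed)
    core = rng.choice(list(_AA), size=core_length)
    all_ids = list(spiral_ids) + list(reference_ids)
    columns: dict[str, list[str]] = {sid: [] for sid in all_ids}
    cursor = 0
    truth_regions: dict[str, list[tuple[int, int]]] = {sid: [] for sid in all_ids}
    counts = {sid: 0 for sid in all_ids}  # ungapped residue counter

    def emit_core(upto: int) -> None:
        nonlocal cursor
        while cursor < upto:
            aa = core[cursor]
            for sid in all_ids:
                columns[sid].append(aa)
                counts[sid] += 1
            cursor += 1

    for k, (pos, length, members) in enumerate(order):
        emit_core(pos)
        members = tuple(members)
        for sid in members:
            if sid not in all_ids:
                raise ValueError(f"unknown member id {sid!r}")
        block = rng.choice(list(_AA), size=length)
        for sid in all_ids:
            if sid in members:
                mlen = member_lengths.get((k, sid), length)
                if not 0 < mlen <= length:
                    raise ValueError("member insertion length must be in 1..length")
                start = counts[sid] + 1
                for c in range(length):
                    if c < mlen:
                        columns[sid].append(str(block[c]))
                        counts[sid] += 1
                    else:
                        columns[sid].append("-")
                truth_regions[sid].append((start, counts[sid]))
            else:
                columns[sid].extend(["-"] * length)
    emit_core(core_length)
    aln = Alignment([(sid, "".join(columns[sid])) for sid in all_ids])
    truth = AlignmentTruth(
        insertions=[(p, l, tuple(m)) for p, l, m in order],
        member_lengths=dict(member_lengths),
        query_regions={sid: regs for sid, regs in truth_regions.items() if regs},
    )
    return aln, truth


def cynd_like_alignment(seed: int = 0) -> tuple[Alignment, AlignmentTruth]:
    """The packaged synthetic fixture emulating the spiral-former alignment.

    A CynD-like member carries both C-surface insertions at their native
    coordinates (55-72, 18 residues; 222-235, 14 residues), a beta-alanine-
    synthase-like member carries region 1 eight residues shorter plus a
    full-length region 2, an oxy-nitrilase-like member carries both at full
    length, and a non-spiral reference carries neither.
    """
    spiral = ["CynD_Bpum", "bAS_Dmel", "oxynit_Syn"]
    reference = ["nonspiral_ref"]
    # region 1 starts at query residue 55 -> after 54 core residues; region 2
    # starts at 222 -> after 54 + (222 - 55 - 18 + 1 - 1) ... i.e. core
    # position 203 so that 203 core + 18 inserted = residue 222 next.
    insertions = [
        (54, 18, tuple(spiral)),
        (203, 14, tuple(spiral)),
    ]
    return simulate_alignment(
        core_length=310,
        insertions=insertions,
        spiral_ids=spiral,
        reference_ids=reference,
        seed=seed,
        member_lengths={(0, "bAS_Dmel"): 10},
    )
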