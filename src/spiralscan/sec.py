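"""Size-exclusion chromatography: calibration, peak detection, oligomer calls.

The workflow mirrors routine SEC practice on a 10/300-format column: fit
log10(mass) against the partition coefficient Kav = (Ve - V0)/(Vt - V0) using
protein standards, convert detected peak positions to apparent masses, round
mass to an oligomer stoichiometry (even-preferred, because the dimer is the
spiral's building block), and classify the elution pattern of each cysteine
mutant against the wild-type 18-mer and the *P. stutzeri* 14-mer reference
positions.  The class vocabulary is the mutant-survey one: 18-mer,
intermediate ~16-mer, 14-mer, multiple smaller species, or void-dominant
(extended/aggregated) elution.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CalibrationStandard",
    "CalibrationFit",
    "MassEstimate",
    "Chromatogram",
    "Peak",
    "ElutionClass",
    "RechromatographyResult",
    "SecError",
    "fit_calibration",
    "apparent_mass",
    "detect_peaks",
    "assign_oligomer",
    "classify_elution_pattern",
    "rechromatography_stability",
    "read_chromatogram_csv",
    "read_standards_csv",
    "SIGMA_STANDARD_MASSES_DA",
    "DEFAULT_MONOMER_MASS_KDA",
]

#: the six gel-filtration marker masses (Da) used for column calibration
SIGMA_STANDARD_MASSES_DA = {
    "carbonic_anhydrase": 29_000,
    "albumin": 66_000,
    "alcohol_dehydrogenase": 150_000,
    "beta_amylase": 200_000,
    "apoferritin": 443_000,
    "thyroglobulin": 669_000,
}

#: CynD monomer mass implied by the internally consistent oligomer ladder
#: (decamer 370 kDa / 10 = hexamer 222 kDa / 6 = dimer 74 kDa / 2 = 37 kDa).
#: SDS-PAGE reads the monomer nearer 40 kDa; this is a config knob, not a law.
DEFAULT_MONOMER_MASS_KDA = 37.0


class SecError(ValueError):
    pass


class ElutionClass(str, enum.Enum):
    MER18 = "mer18"
    MER16_INTERMEDIATE = "mer16_intermediate"
    MER14 = "mer14"
    MULTIPLE_SMALLER = "multiple_smaller"
    EXTENDED_OR_AGGREGATED = "extended_or_aggregated"


@dataclasses.dataclass(frozen=True)
class CalibrationStandard:
    name: str
    mass_da: float
    elution_ml: float

    def __post_init__(self) -> None:
        if self.mass_da <= 0:
            raise SecError(f"standard {self.name}: mass must be positive")


@dataclasses.dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line of log10(mass/Da) on Kav (default) or raw Ve."""

    mode: Literal["kav", "raw_ve"]
    v0_ml: float
    vt_ml: float
    slope: float
    intercept: float
    r_squared: float
    x_min: float
    x_max: float

    def coordinate(self, elution_ml: float) -> float:
        if self.mode == "kav":
            return (elution_ml - self.v0_ml) / (self.vt_ml - self.v0_ml)
        return elution_ml


@dataclasses.dataclass(frozen=True)
class MassEstimate:
    mass_kda: Optional[float]
    in_void: bool
    extrapolated: bool


@dataclasses.dataclass
class Chromatogram:
    """A single-trace chromatogram on a strictly increasing volume grid."""

    volume_ml: np.ndarray
    absorbance_au: np.ndarray
    wavelength_nm: int = 220

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.absorbance_au = np.asarray(self.absorbance_au, dtype=float)
        if self.volume_ml.shape != self.absorbance_au.shape or self.volume_ml.ndim != 1:
            raise SecError("volume and absorbance must be matching 1-D arrays")
        if not np.all(np.diff(self.volume_ml) > 0):
            raise SecError("volume grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance_au)):
            raise SecError("absorbance contains non-finite values")

    @property
    def total_area(self) -> float:
        return float(np.trapezoid(self.absorbance_au, self.volume_ml))


@dataclasses.dataclass
class Peak:
    apex_volume_ml: float
    apex_height_au: float
    area_fraction: float
    in_void: bool
    apparent_mass_kda: Optional[float] = None
    extrapolated: bool = False


def fit_calibration(
    standards: Sequence[CalibrationStandard],
    v0_ml: float,
    vt_ml: float,
    mode: Literal["kav", "raw_ve"] = "kav",
) -> CalibrationFit:
    """Fit log10(mass) against Kav (or raw elution volume).

    Larger species elute earlier, so a physically sensible fit has a negative
    slope; a non-negative slope is rejected as a data error.
    """
    if len(standards) < 3:
        raise SecError("need at least 3 calibration standards")
    if v0_ml >= vt_ml:
        raise SecError("void volume must be smaller than total column volume")
    ve = np.array([s.elution_ml for s in standards])
    if len(np.unique(ve)) != len(ve):
        raise SecError("standards must have distinct elution volumes")
    if mode == "kav":
        x = (ve - v0_ml) / (vt_ml - v0_ml)
    elif mode == "raw_ve":
        x = ve
    else:
        raise SecError(f"unknown calibration mode {mode!r}")
    y = np.log10([s.mass_da for s in standards])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise SecError("calibration slope must be negative (larger species elute earlier)")
    return CalibrationFit(
        mode=mode,
        v0_ml=v0_ml,
        vt_ml=vt_ml,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def apparent_mass(fit: CalibrationFit, elution_ml: float) -> MassEstimate:
    """Apparent mass in kDa at an elution volume.

    At or before the void volume (Kav mode) the species is excluded from the
    matrix and has no defined mass; beyond the standards' range the estimate
    is flagged as extrapolated.
    """
    if fit.mode == "kav" and elution_ml <= fit.v0_ml:
        return MassEstimate(mass_kda=None, in_void=True, extrapolated=False)
    x = fit.coordinate(elution_ml)
    mass_da = 10.0 ** (fit.slope * x + fit.intercept)
    extrapolated = not (fit.x_min <= x <= fit.x_max)
    return MassEstimate(mass_kda=mass_da / 1000.0, in_void=False, extrapolated=extrapolated)


def detect_peaks(
    chromatogram: Chromatogram,
    smoothing_window: int = 5,
    min_prominence_au: Optional[float] = None,
    v0_ml: float = 8.0,
    fit: Optional[CalibrationFit] = None,
    void_tolerance_ml: float = 0.2,
) -> list[Peak]:
    """Detect peaks by moving-average smoothing plus prominence thresholding.

    The default prominence threshold is 1% of the trace maximum.  Peak areas
    are assigned by watershed: the trace is partitioned at the smoothed-signal
    minima between adjacent apexes and each segment's trapezoidal area is
    normalised by the total trace area, so area fractions sum to ~1.  An apex
    at or before ``v0_ml`` (within ``void_tolerance_ml``) is flagged in_void.
    """
    y = chromatogram.absorbance_au
    v = chromatogram.volume_ml
    if y.size < 10:
        raise SecError("need at least 10 grid points")
    if smoothing_window < 1:
        raise SecError("smoothing window must be >= 1")
    kernel = np.ones(smoothing_window) / smoothing_window
    pad = smoothing_window // 2
    padded = np.pad(y, (pad, smoothing_window - 1 - pad), mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    span = float(smooth.max() - smooth.min())
    if span <= 0:
        return []
    prom = min_prominence_au if min_prominence_au is not None else 0.01 * float(smooth.max())
    idx, _ = signal.find_peaks(smooth, prominence=prom)
    if idx.size == 0:
        return []
    # watershed boundaries at the smoothed minima between adjacent apexes
    bounds = [0]
    for a, b in zip(idx[:-1], idx[1:]):
        bounds.append(a + int(np.argmin(smooth[a : b + 1])))
    bounds.append(y.size - 1)
    total = chromatogram.total_area
    peaks = []
    for k, apex in enumerate(idx):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(y[lo : hi + 1], v[lo : hi + 1]))
        apex_v = float(v[apex])
        in_void = apex_v <= v0_ml + void_tolerance_ml
        mass_kda = None
        extrap = False
        if fit is not None and not in_void:
            est = apparent_mass(fit, apex_v)
            mass_kda, extrap = est.mass_kda, est.extrapolated
        peaks.append(
            Peak(
                apex_volume_ml=apex_v,
                apex_height_au=float(y[apex]),
                area_fraction=area / total if total > 0 else 0.0,
                in_void=in_void,
                apparent_mass_kda=mass_kda,
                extrapolated=extrap,
            )
        )
    return peaks


@dataclasses.dataclass(frozen=True)
class OligomerAssignment:
    n: int
    residual: float  # |mass - n * monomer| / monomer


def assign_oligomer(
    mass_kda: float,
    monomer_mass_kda: float = DEFAULT_MONOMER_MASS_KDA,
    prefer_even: bool = True,
) -> OligomerAssignment:
    """Round an apparent mass to an oligomer stoichiometry.

    With ``prefer_even`` (the default: the dimer is the assembly unit, so
    physical species have even subunit counts) an odd nearest integer is
    resolved to the closer even neighbour.
    """
    if mass_kda <= 0 or monomer_mass_kda <= 0:
        raise SecError("masses must be positive")
    ratio = mass_kda / monomer_mass_kda
    n = int(round(ratio))
    if prefer_even and n % 2 == 1:
        lo, hi = n - 1, n + 1
        n = lo if (ratio - lo) <= (hi - ratio) else hi
    n = max(n, 2 if prefer_even else 1)
    residual = abs(mass_kda - n * monomer_mass_kda) / monomer_mass_kda
    return OligomerAssignment(n=n, residual=residual)


def classify_elution_pattern(
    peaks: Sequence[Peak],
    ref_18mer_ml: float,
    ref_14mer_ml: float,
    v0_ml: float = 8.0,
    tolerance_ml: float = 0.3,
    multi_peak_min_fraction: float = 0.15,
) -> ElutionClass:
    """Classify a mutant's elution pattern against the 18-mer / 14-mer refs.

    Dominance is by largest area fraction.  Order of rules:

    1. dominant peak in the void -> extended/aggregated;
    2. >= 2 peaks above ``multi_peak_min_fraction`` area with at least one
       apex beyond the 14-mer position (smaller species) -> multiple smaller;
    3. dominant apex within tolerance of the 18-mer reference -> 18-mer;
    4. within tolerance of the 14-mer reference -> 14-mer;
    5. strictly between the references -> intermediate ~16-mer;
    6. residual: later than the 14-mer -> multiple smaller, earlier than the
       18-mer -> extended/aggregated.
    """
    if not peaks:
        raise SecError("empty peak list")
    if not ref_18mer_ml < ref_14mer_ml:
        raise SecError("18-mer must elute before the 14-mer (larger species elute earlier)")
    dominant = max(peaks, key=lambda p: p.area_fraction)
    if dominant.in_void:
        return ElutionClass.EXTENDED_OR_AGGREGATED
    major = [p for p in peaks if p.area_fraction >= multi_peak_min_fraction]
    if len(major) >= 2 and any(
        p.apex_volume_ml > ref_14mer_ml + tolerance_ml for p in major
    ):
        return ElutionClass.MULTIPLE_SMALLER
    apex = dominant.apex_volume_ml
    if abs(apex - ref_18mer_ml) <= tolerance_ml:
        return ElutionClass.MER18
    if abs(apex - ref_14mer_ml) <= tolerance_ml:
        return ElutionClass.MER14
    if ref_18mer_ml < apex < ref_14mer_ml:
        return ElutionClass.MER16_INTERMEDIATE
    if apex > ref_14mer_ml:
        return ElutionClass.MULTIPLE_SMALLER
    return ElutionClass.EXTENDED_OR_AGGREGATED


@dataclasses.dataclass(frozen=True)
class RechromatographyResult:
    retained_fraction: float
    verdict: Literal["stable", "redistributed"]


def rechromatography_stability(
    original_peaks: Sequence[Peak],
    collection_window_ml: tuple[float, float],
    rerun: Chromatogram,
    v0_ml: float = 8.0,
    stable_threshold: float = 0.5,
) -> RechromatographyResult:
    """Score whether a collected fraction re-elutes inside its own window.

    ``retained_fraction`` is the rerun trace area inside the collection
    window over the total rerun area; a fraction at or above
    ``stable_threshold`` is called stable (the species keeps its oligomeric
    size), otherwise redistributed.
    """
    lo, hi = collection_window_ml
    if not lo < hi:
        raise SecError("collection window must be an increasing (lo, hi) pair")
    v, y = rerun.volume_ml, rerun.absorbance_au
    if not (v[0] <= lo and hi <= v[-1]):
        raise SecError("collection window falls outside the rerun trace range")
    total = rerun.total_area
    if total <= 0:
        raise SecError("rerun trace has zero area")
    grid = np.linspace(lo, hi, 512)
    inside = float(np.trapezoid(np.interp(grid, v, y), grid))
    frac = min(max(inside / total, 0.0), 1.0)
    return RechromatographyResult(
        retained_fraction=frac,
        verdict="stable" if frac >= stable_threshold else "redistributed",
    )


def read_chromatogram_csv(path, wavelength_nm: int = 220) -> Chromatogram:
    """Read a two-column chromatogram CSV with header volume_ml,absorbance_au."""
    df = pd.read_csv(path)
    if not {"volume_ml", "absorbance_au"} <= set(df.columns):
        raise SecError("chromatogram CSV needs columns volume_ml,absorbance_au")
    return Chromatogram(
        df["volume_ml"].to_numpy(), df["absorbance_au"].to_numpy(), wavelength_nm
    )


def read_standards_csv(path) -> list[CalibrationStandard]:
    """Read a calibration table CSV with header name,mass_da,elution_ml."""
    df = pd.read_csv(path)
    if not {"name", "mass_da", "elution_ml"} <= set(df.columns):
        raise SecError("standards CSV needs columns name,mass_da,elution_ml")
    return [
        CalibrationStandard(str(r.name), float(r.mass_da), float(r.elution_ml))
        for r in df.itertuples(index=False)
    ]
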