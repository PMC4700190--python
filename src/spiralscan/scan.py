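"""Cysteine-scan integration: activity, classification and survey counts.

Activity comes from the picric-acid endpoint assay: the A520 colour reports
the cyanide left in the well, so consumed cyanide is (blank - sample) and
relative activity is the linear interpolation between the buffer-only blank
(0%) and wild-type (100%) anchors.  Each scanned position also carries an
elution class from SEC; the survey summary joins the two, counting how many
substitutions per C-surface region keep the wild-type 18-mer pattern and how
many alter the oligomeric state.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional, Sequence

import numpy as np

from .interfaces import RegionDefinition, DEFAULT_REGIONS
from .sec import ElutionClass

__all__ = [
    "ActivityMeasurement",
    "ActivityClass",
    "ActivityResult",
    "Region",
    "MutantRecord",
    "RegionCounts",
    "ScanSummary",
    "relative_activity",
    "classify_activity",
    "summarize_scan",
    "load_scan_fixture",
    "AssayError",
]


class AssayError(ValueError):
    pass


class ActivityClass(str, enum.Enum):
    NORMAL = "normal"
    REDUCED = "reduced"
    MINIMAL = "minimal"


class Region(str, enum.Enum):
    REGION1 = "region1"
    REGION2 = "region2"
    OTHER = "other"


@dataclasses.dataclass(frozen=True)
class ActivityMeasurement:
    sample_id: str
    a520: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.a520 < 0:
            raise AssayError("absorbance cannot be negative")


@dataclasses.dataclass(frozen=True)
class ActivityResult:
    percent: float
    sd: float
    clamped: bool  # sample consumed less cyanide than the blank reads


def _mean_sd(measurements: Sequence[ActivityMeasurement]) -> tuple[float, float]:
    vals = np.array([m.a520 for m in measurements], dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def relative_activity(
    sample: Sequence[ActivityMeasurement],
    wt: Sequence[ActivityMeasurement],
    blank: Sequence[ActivityMeasurement],
) -> ActivityResult:
    """Percent activity relative to wild type from endpoint A520 readings.

    ``100 * (blank - sample) / (blank - wt)`` on replicate means: the blank
    anchors 0% (no cyanide consumed) and wild type anchors 100%.  Values are
    clamped below at zero with a flag.  The sd is propagated from replicate
    standard deviations by the delta method.
    """
    if not sample or not wt or not blank:
        raise AssayError("sample, wt and blank measurement sets must be non-empty")
    ms, ss = _mean_sd(sample)
    mw, sw = _mean_sd(wt)
    mb, sb = _mean_sd(blank)
    denom = mb - mw
    if denom <= 0:
        raise AssayError("assay failure: blank A520 must exceed wild-type A520")
    pct = 100.0 * (mb - ms) / denom
    # delta method: d/dms, d/dmw, d/dmb of the formula above
    d_ms = -100.0 / denom
    d_mw = 100.0 * (mb - ms) / denom**2
    d_mb = 100.0 * (ms - mw) / denom**2
    var = (d_ms * ss) ** 2 + (d_mw * sw) ** 2 + (d_mb * sb) ** 2
    clamped = pct < 0
    return ActivityResult(percent=max(pct, 0.0), sd=float(np.sqrt(var)), clamped=clamped)


def classify_activity(
    percent: float,
    reduced_threshold: float = 50.0,
    minimal_threshold: float = 10.0,
) -> ActivityClass:
    """Three-way activity call: < minimal -> minimal, <= reduced -> reduced.

    The boundaries follow the survey's phrasing: "at or below 50%" is
    reduced (inclusive), "below 10%" is minimal (exclusive at 10).
    """
    if percent < 0:
        raise AssayError("percent activity cannot be negative")
    if percent < minimal_threshold:
        return ActivityClass.MINIMAL
    if percent <= reduced_threshold:
        return ActivityClass.REDUCED
    return ActivityClass.NORMAL


@dataclasses.dataclass(frozen=True)
class MutantRecord:
    mutant_id: str
    region: Region
    position: int
    substitution: str
    elution_class: ElutionClass
    relative_activity_pct: Optional[float] = None
    activity_class: Optional[ActivityClass] = None


@dataclasses.dataclass
class RegionCounts:
    total: int
    wild_type_pattern: int
    altered: int
    wild_type_ids: list[str]
    altered_ids: list[str]


@dataclasses.dataclass
class ScanSummary:
    per_region: dict[str, RegionCounts]
    altered_total: int
    altered_ids: list[str]
    joint: dict[tuple[str, bool], list[str]]  # (activity class, altered?) -> ids


def summarize_scan(
    records: Sequence[MutantRecord],
    regions: Sequence[RegionDefinition] = DEFAULT_REGIONS,
) -> ScanSummary:
    """Aggregate per-region and joint activity/oligomer counts.

    Wild-type pattern means the 18-mer elution class; every other class is an
    oligomerization alteration.  Records outside the declared regions (e.g.
    the wild-type control) are excluded from the per-region tallies.
    """
    ids = [r.mutant_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AssayError(f"duplicate mutant ids: {dupes}")
    region_names = {Region.REGION1: "region1", Region.REGION2: "region2"}
    for rec in records:
        if rec.region in region_names:
            rdef = next(r for r in regions if r.name == region_names[rec.region])
            if rec.position not in rdef:
                raise AssayError(
                    f"{rec.mutant_id}: position {rec.position} outside {rdef.name} "
                    f"({rdef.start}-{rdef.end})"
                )
    per_region: dict[str, RegionCounts] = {}
    for region_enum, name in region_names.items():
        members = sorted(
            (r for r in records if r.region is region_enum), key=lambda r: r.position
        )
        wt_ids = [r.mutant_id for r in members if r.elution_class is ElutionClass.MER18]
        alt_ids = [r.mutant_id for r in members if r.elution_class is not ElutionClass.MER18]
        per_region[name] = RegionCounts(
            total=len(members),
            wild_type_pattern=len(wt_ids),
            altered=len(alt_ids),
            wild_type_ids=wt_ids,
            altered_ids=alt_ids,
        )
    scanned = sorted(
        (r for r in records if r.region is not Region.OTHER), key=lambda r: (r.region.value, r.position)
    )
    altered_ids = [r.mutant_id for r in scanned if r.elution_class is not ElutionClass.MER18]
    joint: dict[tuple[str, bool], list[str]] = {}
    for r in scanned:
        if r.activity_class is None:
            continue
        key = (r.activity_class.value, r.elution_class is not ElutionClass.MER18)
        joint.setdefault(key, []).append(r.mutant_id)
    return ScanSummary(
        per_region=per_region,
        altered_total=len(altered_ids),
        altered_ids=altered_ids,
        joint=joint,
    )


# --- packaged cysteine-scan survey fixture -------------------------------
#
# Elution classes for the 32 C-surface constructs plus the wild-type control,
# as read off the mutant survey: per-position cysteine substitutions across
# region 1 (P55-E72) and region 2 (E222-E235), the native C225 changed to
# alanine.  Activity classes encode the survey's threshold statements
# (reduced = at or below 50% of wild type, minimal = below 10%); numeric
# percentages were not published per mutant, so relative_activity_pct is None.

_N, _R, _M = ActivityClass.NORMAL, ActivityClass.REDUCED, ActivityClass.MINIMAL
_E18 = ElutionClass.MER18
_E16 = ElutionClass.MER16_INTERMEDIATE
_E14 = ElutionClass.MER14
_EMS = ElutionClass.MULTIPLE_SMALLER
_EXT = ElutionClass.EXTENDED_OR_AGGREGATED

_REGION1_WT_SEQ = "PWFAFIGHPEYTRKFYHE"  # residues 55-72
_REGION2_WT_SEQ = "EMICLTQEQRDYFE"  # residues 222-235

_FIXTURE_ROWS: list[tuple[str, str, int, ElutionClass, ActivityClass]] = [
    # region 1 (P55-E72)
    ("P55C", "region1", 55, _E18, _R),
    ("W56C", "region1", 56, _E16, _N),
    ("F57C", "region1", 57, _E14, _R),
    ("A58C", "region1", 58, _E18, _N),
    ("F59C", "region1", 59, _E18, _N),
    ("I60C", "region1", 60, _E18, _N),
    ("G61C", "region1", 61, _E14, _R),
    ("H62C", "region1", 62, _E18, _N),
    ("P63C", "region1", 63, _E18, _N),
    ("E64C", "region1", 64, _E16, _R),
    ("Y65C", "region1", 65, _E18, _R),
    ("T66C", "region1", 66, _E16, _R),
    ("R67C", "region1", 67, _EMS, _M),
    ("K68C", "region1", 68, _E18, _N),
    ("F69C", "region1", 69, _E16, _R),
    ("Y70C", "region1", 70, _E16, _M),
    ("H71C", "region1", 71, _E16, _N),
    ("E72C", "region1", 72, _E18, _N),
    # region 2 (E222-E235); the native cysteine 225 is scanned as C225A
    ("E222C", "region2", 222, _E18, _N),
    ("M223C", "region2", 223, _E18, _N),
    ("I224C", "region2", 224, _E18, _N),
    ("C225A", "region2", 225, _E18, _N),
    ("L226C", "region2", 226, _E18, _N),
    ("T227C", "region2", 227, _E18, _N),
    ("Q228C", "region2", 228, _EXT, _N),
    ("E229C", "region2", 229, _E18, _N),
    ("Q230C", "region2", 230, _E18, _R),
    ("R231C", "region2", 231, _E18, _N),
    ("D232C", "region2", 232, _E18, _N),
    ("Y233C", "region2", 233, _E16, _N),
    ("F234C", "region2", 234, _E16, _N),
    ("E235C", "region2", 235, _E18, _R),
]


def load_scan_fixture() -> tuple[list[MutantRecord], list[RegionDefinition]]:
    """The packaged cysteine-scan survey: 32 constructs plus wild type.

    Returns the per-mutant records (elution class and threshold-level
    activity class) and the two C-surface region definitions.
    """
    records = [
        MutantRecord(
            mutant_id=mid,
            region=Region(region),
            position=pos,
            substitution=mid[-1],
            elution_class=elution,
            activity_class=act,
        )
        for mid, region, pos, elution, act in _FIXTURE_ROWS
    ]
    records.append(
        MutantRecord(
            mutant_id="wt",
            region=Region.OTHER,
            position=0,
            substitution="",
            elution_class=_E18,
            activity_class=_N,
        )
    )
    return records, list(DEFAULT_REGIONS)
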