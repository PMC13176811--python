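"""Segmental shape metrics of the ascending aorta.

The ascending aorta is divided into 2.5 cm centerline-length segments: the
proximal plane of segment A sits at the sinotubular junction (STJ) and the
distal plane of segment C at the brachiocephalic trunk (BT).  Each segment
carries six perpendicular planes indented 5 mm from each other and from the
segment boundaries.  From the per-plane Dmax/Dmin this module computes

* the segment *relative difference* — segment A: (Dmax plane6 − Dmax
  plane1)/Dmax plane6; segment C: (Dmax plane1 − Dmax plane6)/Dmax plane1 —
  positive values indicating the expected orientation (A widens distally =
  reversed funnel, C narrows distally = funnel);
* per-plane *ovality* (Dmax − Dmin)/Dmax with the 5 % oval/circular
  threshold;
* the funnel / reversed-funnel / cylindrical classification;
* the location of the maximal diameter along the vessel (arc-length
  fraction of total length);
* per-plane systolic-minus-diastolic diameter offsets.

All metrics can be evaluated either on pipeline PlaneMeasurements from a
rasterized mask or analytically from an :class:`~aortamorph.synthetic.AortaSpec`
profile, which the test-suite uses to cross-check the geometric pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Centerline, PlaneMeasurement, measure_plane
from .synthetic import AortaSpec

__all__ = [
    "SegmentProfile",
    "ShapeReport",
    "SEGMENT_SPAN_MM",
    "PLANE_STEP_MM",
    "place_segments",
    "measure_segment",
    "relative_difference",
    "absolute_difference",
    "ovality",
    "is_oval",
    "classify_segment",
    "locate_max_diameter",
    "sweep_planes",
    "phase_offset",
    "segment_profile_from_spec",
    "shape_report",
]

SEGMENT_SPAN_MM = 25.0
PLANE_STEP_MM = 5.0
N_PLANES = 6
OVAL_THRESHOLD = 0.05


@dataclass(frozen=True)
class SegmentProfile:
    """Six plane measurements of one segment, ordered proximal to distal."""

    segment_label: str  # "A" or "C"
    planes: tuple  # 6 PlaneMeasurements
    phase: str

    def __post_init__(self) -> None:
        if self.segment_label not in ("A", "C"):
            raise ValueError("segment_label must be 'A' or 'C'")
        if len(self.planes) != N_PLANES:
            raise ValueError(f"a segment holds exactly {N_PLANES} planes")
        s = np.array([p.arclength_mm for p in self.planes])
        if np.any(np.abs(np.diff(s) - PLANE_STEP_MM) > 0.1):
            raise ValueError("plane spacing must be 5.0 mm +/- 0.1 mm")

    @property
    def d_max(self) -> np.ndarray:
        return np.array([p.d_max for p in self.planes])

    @property
    def d_min(self) -> np.ndarray:
        return np.array([p.d_min for p in self.planes])

    @property
    def area(self) -> np.ndarray:
        return np.array([p.area for p in self.planes])


@dataclass(frozen=True)
class ShapeReport:
    """All shape metrics of one aorta (paired phases)."""

    aa_length_mm: float
    max_diameter_mm: float
    max_diameter_location_fraction: float
    ovality_by_plane: dict  # {segment: array of 6 fractions} (systole)
    relative_difference_A: float
    relative_difference_C: float
    absolute_difference_A_mm: float
    absolute_difference_C_mm: float
    shape_class_A: str
    shape_class_C: str
    phase_offsets_mm: dict  # {segment: array of 6 systolic-minus-diastolic Dmax}

    def to_dict(self) -> dict:
        return {
            "aa_length_mm": self.aa_length_mm,
            "max_diameter_mm": self.max_diameter_mm,
            "max_diameter_location_fraction": self.max_diameter_location_fraction,
            "ovality_by_plane": {k: list(map(float, v)) for k, v in self.ovality_by_plane.items()},
            "relative_difference_A": self.relative_difference_A,
            "relative_difference_C": self.relative_difference_C,
            "absolute_difference_A_mm": self.absolute_difference_A_mm,
            "absolute_difference_C_mm": self.absolute_difference_C_mm,
            "shape_class_A": self.shape_class_A,
            "shape_class_C": self.shape_class_C,
            "phase_offsets_mm": {k: list(map(float, v)) for k, v in self.phase_offsets_mm.items()},
        }


def place_segments(centerline_or_length) -> dict[str, np.ndarray]:
    """Arc-length positions (mm) of the six planes of segments A and C.

    Segment A spans [0, 25] mm from the STJ; segment C spans the last 25 mm
    up to the BT; planes are indented 5 mm.
    """
    L = (
        centerline_or_length.total_length
        if isinstance(centerline_or_length, Centerline)
        else float(centerline_or_length)
    )
    if L < 2 * SEGMENT_SPAN_MM:
        raise ValueError(
            f"segments overlap: total length {L:.1f} mm < {2 * SEGMENT_SPAN_MM:.0f} mm"
        )
    a = np.arange(N_PLANES) * PLANE_STEP_MM
    return {"A": a, "C": L - SEGMENT_SPAN_MM + a}


def measure_segment(mask_img, centerline: Centerline, label: str, phase: str) -> SegmentProfile:
    """Measure the six planes of segment ``label`` on a rasterized mask."""
    positions = place_segments(centerline)[label]
    planes = tuple(measure_plane(mask_img, centerline, s) for s in positions)
    return SegmentProfile(segment_label=label, planes=planes, phase=phase)


def relative_difference(profile: SegmentProfile) -> float:
    """Label-specific relative diameter difference of boundary planes.

    Segment A: (plane6 − plane1)/plane6; segment C: (plane1 − plane6)/plane1,
    on systolic-phase Dmax by convention (callers pass the systolic profile).
    """
    d1, d6 = profile.d_max[0], profile.d_max[-1]
    if profile.segment_label == "A":
        return float((d6 - d1) / d6)
    return float((d1 - d6) / d1)


def absolute_difference(profile: SegmentProfile) -> float:
    """Distal-minus-proximal Dmax (mm); sign follows plane ordering."""
    return float(profile.d_max[-1] - profile.d_max[0])


def ovality(plane: PlaneMeasurement | tuple[float, float]) -> float:
    """Relative Dmax/Dmin gap of one plane: (d_max − d_min)/d_max.

    Planes with ovality >= 5 % are classified oval, else circular.
    """
    if hasattr(plane, "d_max"):
        d_max, d_min = plane.d_max, plane.d_min
    else:
        d_max, d_min = plane
    if not d_max >= d_min > 0:
        raise ValueError("require d_max >= d_min > 0")
    return float((d_max - d_min) / d_max)


def is_oval(plane) -> bool:
    return ovality(plane) >= OVAL_THRESHOLD


def classify_segment(profile: SegmentProfile, tol: float = 0.02) -> str:
    """Classify a segment as funnel / reversed_funnel / cylindrical.

    Segment A widening distally beyond ``tol`` (relative to the larger,
    distal plane) is a reversed funnel; segment C narrowing distally is a
    funnel.  Differences below ``tol`` are cylindrical.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    rd = relative_difference(profile)
    if abs(rd) <= tol:
        return "cylindrical"
    if profile.segment_label == "A":
        return "reversed_funnel" if rd > 0 else "funnel"
    return "funnel" if rd > 0 else "reversed_funnel"


def sweep_planes(mask_img, centerline: Centerline, step_mm: float = 1.0) -> list[PlaneMeasurement]:
    """Measure planes along the whole centerline at ``step_mm`` spacing."""
    L = centerline.total_length
    positions = np.arange(0.0, L + 1e-9, step_mm)
    if positions[-1] < L - 1e-6:
        positions = np.r_[positions, L]
    return [measure_plane(mask_img, centerline, s) for s in positions]


def locate_max_diameter(planes: list[PlaneMeasurement], total_length: float | None = None
                        ) -> tuple[float, float]:
    """Maximal Dmax over a dense plane sweep and its arc-length fraction.

    Ties break toward the most proximal station.  ``total_length`` defaults
    to the arc length of the last plane.
    """
    if len(planes) < 25:
        raise ValueError("need a dense sweep (>= 25 stations)")
    d = np.array([p.d_max for p in planes])
    s = np.array([p.arclength_mm for p in planes])
    L = float(total_length) if total_length is not None else float(s[-1])
    i = int(np.argmax(d))  # argmax returns the first (most proximal) maximum
    return float(d[i]), float(s[i] / L)


def phase_offset(systolic: SegmentProfile, diastolic: SegmentProfile,
                 position_atol_mm: float = 1.0) -> np.ndarray:
    """Per-plane systolic-minus-diastolic Dmax differences (mm).

    ``position_atol_mm`` allows for the sub-millimetre arc-length drift
    between independently extracted phase centerlines.
    """
    if systolic.segment_label != diastolic.segment_label:
        raise ValueError("profiles belong to different segments")
    s_sys = np.array([p.arclength_mm for p in systolic.planes])
    s_dia = np.array([p.arclength_mm for p in diastolic.planes])
    if np.any(np.abs(s_sys - s_dia) > position_atol_mm):
        raise ValueError("plane positions differ between phases")
    return systolic.d_max - diastolic.d_max


# ---------------------------------------------------------------------------
# analytic evaluation on parametric specs
# ---------------------------------------------------------------------------

class _AnalyticPlane:
    """Duck-typed plane measurement evaluated from an AortaSpec profile."""

    def __init__(self, spec: AortaSpec, s_mm: float):
        f = np.clip(s_mm / spec.total_length, 0.0, 1.0)
        self.arclength_mm = float(s_mm)
        self.d_max = float(spec.dmax(f))
        self.d_min = float(spec.dmin(f))
        self.area = float(np.pi / 4 * self.d_max * self.d_min)


def segment_profile_from_spec(spec: AortaSpec, label: str) -> SegmentProfile:
    """Segment profile evaluated directly from the parametric profiles."""
    positions = place_segments(spec.total_length)[label]
    planes = tuple(_AnalyticPlane(spec, s) for s in positions)
    return SegmentProfile(segment_label=label, planes=planes, phase=spec.phase)


def shape_report(
    profiles_sys: dict[str, SegmentProfile],
    profiles_dia: dict[str, SegmentProfile] | None,
    aa_length_mm: float,
    max_diameter_mm: float,
    max_diameter_location_fraction: float,
) -> ShapeReport:
    """Assemble the full per-aorta shape report from measured profiles.

    ``profiles_dia`` may be None (single-phase input); phase offsets are
    then omitted.
    """
    return ShapeReport(
        aa_length_mm=float(aa_length_mm),
        max_diameter_mm=float(max_diameter_mm),
        max_diameter_location_fraction=float(max_diameter_location_fraction),
        ovality_by_plane={
            k: np.array([ovality(p) for p in prof.planes]) for k, prof in profiles_sys.items()
        },
        relative_difference_A=relative_difference(profiles_sys["A"]),
        relative_difference_C=relative_difference(profiles_sys["C"]),
        absolute_difference_A_mm=absolute_difference(profiles_sys["A"]),
        absolute_difference_C_mm=absolute_difference(profiles_sys["C"]),
        shape_class_A=classify_segment(profiles_sys["A"]),
        shape_class_C=classify_segment(profiles_sys["C"]),
        phase_offsets_mm=(
            {}
            if profiles_dia is None
            else {k: phase_offset(profiles_sys[k], profiles_dia[k]) for k in profiles_sys}
        ),
    )
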