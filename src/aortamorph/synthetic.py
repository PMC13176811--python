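"""Parametric ascending-aorta phantoms and virtual cohorts.

The ascending aorta (AA) is modelled as an elliptical tube swept along a
curved centerline running from the sinotubular junction (STJ, arc-length
fraction ``s = 0``) to the brachiocephalic trunk (BT, ``s = 1``).  Four
smooth profiles parameterise the tube as functions of ``s``:

* ``dmax(s)``       maximal cross-sectional diameter, mm
* ``ovality(s)``    relative gap between maximal and minimal diameter,
                    ``(Dmax - Dmin)/Dmax``
* ``phase_offset(s)`` systolic-minus-diastolic diameter decrement, mm
* ``rotation(s)``   in-plane major-axis angle, rad (0 by default)

Profiles are monotone piecewise-cubic (PCHIP) interpolants through a small
set of calibration knots, so archetype diameters at the knots are exact and
no overshoot can create spurious local maxima.  Two archetype presets are
provided: a nondilated aorta ("ndg") and one with a mid-aortic dilatation
("dg"), each in systole and diastole.  ``sample_cohort`` draws virtual
patients (covariates + per-patient geometry) around these presets, and
``rasterize`` turns any spec into a binary lumen mask with NIfTI-compatible
spacing so the full image-analysis pipeline can run on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d
from scipy.spatial import cKDTree

__all__ = [
    "AortaSpec",
    "PatientRecord",
    "ELIGIBILITY_FLAGS",
    "make_archetype",
    "sample_cohort",
    "rasterize",
    "simulate_readers",
]

BEND_ANGLE_RAD = np.pi / 3  # ~60 deg total centerline bend

ELIGIBILITY_FLAGS = (
    "lvef_below_30",
    "calcinosis_over_30pct",
    "connective_tissue_disease",
    "annuloaortic_ectasia",
    "prior_heart_surgery",
    "incomplete_imaging",
)


def _pchip(knots: tuple[tuple[float, float], ...]) -> PchipInterpolator:
    xs, ys = zip(*knots)
    return PchipInterpolator(np.asarray(xs), np.asarray(ys))


@dataclass(frozen=True)
class AortaSpec:
    """Ground-truth geometry of one aorta in one cardiac phase.

    ``diameter_knots`` describe the *systolic* Dmax profile; in diastole
    ``dmax`` subtracts the phase-offset profile, mirroring the small
    pulsatile diameter change between 40 % RR (systole) and 75 % RR
    (diastole) reconstructions.
    """

    name: str
    phase: str  # "systole" or "diastole"
    total_length: float  # mm, STJ -> BT arc length
    centerline_control_points: np.ndarray  # (n, 3) mm
    diameter_knots: tuple[tuple[float, float], ...]
    ovality_knots: tuple[tuple[float, float], ...]
    phase_offset_knots: tuple[tuple[float, float], ...]
    rotation_knots: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 0.0))

    def __post_init__(self) -> None:
        if self.phase not in ("systole", "diastole"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.total_length > 50.0:
            raise ValueError("total_length must exceed 50 mm")
        s = np.linspace(0.0, 1.0, 513)
        d = self.dmax(s)
        if d.min() < 20.0 or d.max() > 60.0:
            raise ValueError("diameter profile must stay within [20, 60] mm")
        if self.ovality(s).min() < 0.0 or self.ovality(s).max() > 0.15:
            raise ValueError("ovality profile must stay within [0, 0.15]")
        off = self.phase_offset(s)
        if off.min() < 0.0 or off.max() > 1.0:
            raise ValueError("phase offsets must stay within [0, 1] mm")

    # -- profile evaluation -------------------------------------------------
    def dmax(self, s):
        """Maximal diameter (mm) at arc-length fraction ``s``."""
        base = _pchip(self.diameter_knots)(s)
        if self.phase == "diastole":
            base = base - self.phase_offset(s)
        return base

    def dmin(self, s):
        """Minimal diameter (mm) at arc-length fraction ``s``."""
        return self.dmax(s) * (1.0 - self.ovality(s))

    def ovality(self, s):
        return _pchip(self.ovality_knots)(s)

    def phase_offset(self, s):
        return _pchip(self.phase_offset_knots)(s)

    def rotation(self, s):
        return _pchip(self.rotation_knots)(s)

    # -- derived ------------------------------------------------------------
    def max_diameter(self, n: int = 2049) -> float:
        s = np.linspace(0.0, 1.0, n)
        return float(self.dmax(s).max())

    @property
    def is_dilated(self) -> bool:
        return 40.0 <= self.max_diameter() <= 50.0


@dataclass(frozen=True)
class PatientRecord:
    """Covariates, group label and paired-phase geometry of one virtual patient."""

    patient_id: str
    age: int
    sex: str  # "male" or "female"
    bsa: float  # m^2, DuBois
    group: str  # "dilated" or "nondilated"
    eligibility_flags: frozenset = field(default_factory=frozenset)
    aorta_systole: AortaSpec | None = None
    aorta_diastole: AortaSpec | None = None

    def __post_init__(self) -> None:
        if self.bsa <= 0:
            raise ValueError("bsa must be positive")
        if self.group not in ("dilated", "nondilated"):
            raise ValueError(f"unknown group {self.group!r}")
        bad = set(self.eligibility_flags) - set(ELIGIBILITY_FLAGS)
        if bad:
            raise ValueError(f"unknown eligibility flags: {sorted(bad)}")

    @property
    def eligible(self) -> bool:
        return not self.eligibility_flags


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------

# Calibration knots: (arc-length fraction, value).  Diameter knots pin the
# STJ plane, the distal segment-A boundary plane (25 mm from the STJ), the
# unique interior diameter peak, the proximal segment-C boundary plane
# (25 mm before the BT) and the BT plane.
_ARCHETYPES = {
    "nondilated": dict(
        total_length=67.0,
        diameter_knots=(
            (0.0, 31.9),
            (25.0 / 67.0, 37.1),
            (0.50, 37.2),
            (42.0 / 67.0, 35.4),
            (1.0, 33.7),
        ),
        ovality_knots=(
            (0.0, 0.089),
            (25.0 / 67.0, 0.048),
            (42.0 / 67.0, 0.047),
            (1.0, 0.047),
        ),
        # pulsatile diameter change tapers from STJ to BT
        phase_offset_knots=((0.0, 0.3), (1.0, 0.2)),
    ),
    "dilated": dict(
        total_length=79.0,
        diameter_knots=(
            (0.0, 34.6),
            (25.0 / 79.0, 42.2),
            (0.48, 43.1),
            (54.0 / 79.0, 42.3),
            (1.0, 39.0),
        ),
        ovality_knots=(
            (0.0, 0.094),
            (25.0 / 79.0, 0.056),
            (54.0 / 79.0, 0.056),
            (1.0, 0.056),
        ),
        phase_offset_knots=((0.0, 0.5), (1.0, 0.3)),
    ),
}

_GROUP_SHORT = {"nondilated": "ndg", "dilated": "dg"}


def _arc_control_points(total_length: float, n: int = 17) -> np.ndarray:
    """Control points on a planar circular arc of the given arc length.

    The arc bends by ``BEND_ANGLE_RAD`` over its length, a representative
    ascending-aorta curvature; a straight tube would leave the
    perpendicular-plane logic untested.
    """
    radius = total_length / BEND_ANGLE_RAD
    phi = np.linspace(0.0, BEND_ANGLE_RAD, n)
    pts = np.column_stack(
        [radius * np.sin(phi), np.zeros_like(phi), radius * (1.0 - np.cos(phi))]
    )
    return pts


def make_archetype(group: str, phase: str) -> AortaSpec:
    """Return the noise-free preset for ``group`` in ``phase``.

    Preset names follow ``"<group-short>-<phase>"``, e.g. ``"dg-systole"``.
    """
    if group not in _ARCHETYPES:
        raise ValueError(f"unknown group {group!r}")
    cfg = _ARCHETYPES[group]
    return AortaSpec(
        name=f"{_GROUP_SHORT[group]}-{phase}",
        phase=phase,
        total_length=cfg["total_length"],
        centerline_control_points=_arc_control_points(cfg["total_length"]),
        diameter_knots=cfg["diameter_knots"],
        ovality_knots=cfg["ovality_knots"],
        phase_offset_knots=cfg["phase_offset_knots"],
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

# Lognormal scale spread of the per-patient diameter multiplier, calibrated so
# the quartile ratio of peak diameters matches the reported group IQRs
# (nondilated 36.0 [33.8, 37.8], dilated 43.1 [41.8, 45.5] mm):
# sigma = ln(Q3/Q1) / (2 * 0.6745).
_DIAM_SIGMA = {
    "nondilated": np.log(37.8 / 33.8) / 1.349,
    "dilated": np.log(45.5 / 41.8) / 1.349,
}
# Length SD from IQR/1.349 (nondilated IQR 61-71 mm, dilated 70-85 mm).
_LENGTH_SD = {"nondilated": 10.0 / 1.349, "dilated": 15.0 / 1.349}

# Monotone quantile anchors for age (years): median 80, IQR [78, 85].
_AGE_QUANTILE_ANCHORS = ((0.005, 68.0), (0.25, 78.0), (0.5, 80.0), (0.75, 85.0), (0.995, 97.0))
_P_MALE = 0.54
_BSA_MEAN, _BSA_SD, _BSA_LO, _BSA_HI = 1.8, 0.15, 1.4, 2.4


def _sample_age(rng: np.random.Generator) -> int:
    q = _pchip(_AGE_QUANTILE_ANCHORS)
    u = rng.uniform(0.005, 0.995)
    return int(np.round(q(u)))


def _scaled_spec(group: str, phase: str, scale: float, length: float,
                 offset_knots: tuple, name: str) -> AortaSpec:
    cfg = _ARCHETYPES[group]
    dk = tuple((s, v * scale) for s, v in cfg["diameter_knots"])
    return AortaSpec(
        name=name,
        phase=phase,
        total_length=length,
        centerline_control_points=_arc_control_points(length),
        diameter_knots=dk,
        ovality_knots=cfg["ovality_knots"],
        phase_offset_knots=offset_knots,
    )


def sample_cohort(
    n_dilated: int,
    n_nondilated: int,
    seed: int,
    exclusion_rate: float = 0.0,
) -> list[PatientRecord]:
    """Draw a reproducible virtual cohort around the group archetypes.

    Each patient receives a multiplicative diameter scale (lognormal, median
    1), a length drawn around the archetype length, covariates (age, sex,
    BSA), and stochastic per-plane systole/diastole offsets uniform in
    [0.1, 0.7] mm.  Scales are rejection-sampled so the group label always
    satisfies the diameter criterion (dilated: peak in [40, 50] mm;
    nondilated: peak < 40 mm).  With ``exclusion_rate > 0`` a patient is
    flagged with one randomly chosen exclusion reason at that rate.
    """
    if n_dilated < 1 or n_nondilated < 1:
        raise ValueError("cohort counts must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    groups = ["dilated"] * n_dilated + ["nondilated"] * n_nondilated
    for i, group in enumerate(groups):
        peak0 = max(v for _, v in _ARCHETYPES[group]["diameter_knots"])
        lo, hi = (40.0, 50.0) if group == "dilated" else (25.0, 40.0 - 1e-9)
        for _ in range(1000):
            scale = float(np.exp(rng.normal(0.0, _DIAM_SIGMA[group])))
            if lo <= peak0 * scale <= hi:
                break
        else:  # pragma: no cover - bounded rejection loop
            raise RuntimeError("diameter-scale rejection sampling failed")
        length0 = _ARCHETYPES[group]["total_length"]
        length = float(np.clip(rng.normal(length0, _LENGTH_SD[group]), 52.0, 110.0))
        frac = np.linspace(0.0, 1.0, 13)
        offsets = tuple(zip(frac, rng.uniform(0.1, 0.7, size=frac.size)))
        sex = "male" if rng.random() < _P_MALE else "female"
        bsa = float(np.clip(rng.normal(_BSA_MEAN, _BSA_SD), _BSA_LO, _BSA_HI))
        flags = frozenset()
        if exclusion_rate > 0 and rng.random() < exclusion_rate:
            flags = frozenset([ELIGIBILITY_FLAGS[rng.integers(len(ELIGIBILITY_FLAGS))]])
        pid = f"{_GROUP_SHORT[group]}-{i:04d}"
        records.append(
            PatientRecord(
                patient_id=pid,
                age=_sample_age(rng),
                sex=sex,
                bsa=bsa,
                group=group,
                eligibility_flags=flags,
                aorta_systole=_scaled_spec(group, "systole", scale, length, offsets, pid),
                aorta_diastole=_scaled_spec(group, "diastole", scale, length, offsets, pid),
            )
        )
    return records


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _dense_centerline(spec: AortaSpec, step_mm: float = 0.1):
    """Arc-length-resampled centerline points, fractions and PT frames."""
    cp = np.asarray(spec.centerline_control_points, float)
    if cp.shape[0] < 2 or spec.total_length <= 0:
        raise ValueError("degenerate centerline")
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
    if chord[-1] <= 0:
        raise ValueError("degenerate centerline (zero length)")
    interp = interp1d(chord, cp, axis=0, kind="cubic")
    t_dense = np.linspace(0.0, chord[-1], max(2000, int(chord[-1] / 0.02)))
    p_dense = interp(t_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arclen = np.r_[0.0, np.cumsum(seg)]
    total = arclen[-1]
    n_out = max(int(np.ceil(total / step_mm)) + 1, 8)
    s_out = np.linspace(0.0, total, n_out)
    pts = interp1d(arclen, p_dense, axis=0)(s_out)

    tangents = np.gradient(pts, s_out, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # parallel-transport (rotation-minimising) normal frame
    normals = np.empty_like(tangents)
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = np.cross(t0, np.cross(ref, t0))
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(tangents)):
        n = normals[i - 1] - (normals[i - 1] @ tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return pts, s_out, tangents, normals, binormals


def rasterize(spec: AortaSpec, voxel_mm: float):
    """Voxelise the swept elliptical tube into a binary NIfTI mask.

    A voxel is foreground when its center lies inside the tube; the tube is
    capped flush with the perpendicular planes at the STJ and BT.  Returns
    ``(image, landmarks)`` where ``landmarks`` holds the STJ and BT world
    coordinates (mm).
    """
    if not 0.3 <= voxel_mm <= 1.0:
        raise ValueError("voxel_mm must lie in [0.3, 1.0]")
    pts, s, tangents, normals, binormals = _dense_centerline(spec)
    total = s[-1]
    frac = s / total
    rmax = 0.5 * float(np.max(spec.dmax(np.linspace(0, 1, 257)))) + 1.0

    lo = pts.min(axis=0) - rmax - 2.0
    hi = pts.max(axis=0) + rmax + 2.0
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    origin = lo

    tree = cKDTree(pts)
    mask = np.zeros(shape, dtype=np.uint8)
    xs = origin[0] + voxel_mm * np.arange(shape[0])
    ys = origin[1] + voxel_mm * np.arange(shape[1])
    zs = origin[2] + voxel_mm * np.arange(shape[2])

    # process in z-slabs to bound memory
    slab = max(1, int(4e6 // (shape[0] * shape[1])))
    for z0 in range(0, shape[2], slab):
        z1 = min(z0 + slab, shape[2])
        gx, gy, gz = np.meshgrid(xs, ys, zs[z0:z1], indexing="ij")
        pts_q = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        dist, idx = tree.query(pts_q, distance_upper_bound=rmax + 0.5)
        hit = np.isfinite(dist)
        if not hit.any():
            continue
        idx_h = idx[hit]
        d = pts_q[hit] - pts[idx_h]
        w = np.einsum("ij,ij->i", d, tangents[idx_h])
        s_ref = s[idx_h] + w
        inside_len = (s_ref >= 0.0) & (s_ref <= total)
        u = np.einsum("ij,ij->i", d, normals[idx_h])
        v = np.einsum("ij,ij->i", d, binormals[idx_h])
        f = np.clip(s_ref / total, 0.0, 1.0)
        a = 0.5 * spec.dmax(f)
        b = a * (1.0 - spec.ovality(f))
        th = spec.rotation(f)
        ur = u * np.cos(th) + v * np.sin(th)
        vr = -u * np.sin(th) + v * np.cos(th)
        inside = inside_len & ((ur / a) ** 2 + (vr / b) ** 2 <= 1.0)
        vol = np.zeros(pts_q.shape[0], dtype=np.uint8)
        vol[hit] = inside.astype(np.uint8)
        mask[:, :, z0:z1] = vol.reshape(shape[0], shape[1], z1 - z0)

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(mask, affine)
    img.header.set_zooms((voxel_mm,) * 3)
    landmarks = {"stj": pts[0].tolist(), "bt": pts[-1].tolist()}
    return img, landmarks


# ---------------------------------------------------------------------------
# reader simulation
# ---------------------------------------------------------------------------

def simulate_readers(measurements, noise_sd_mm: float = 0.3, seed: int = 0):
    """Simulate two independent readers of the same measurement series.

    Adds independent zero-mean Gaussian noise (SD ``noise_sd_mm``) per
    reader and per measurement; emulates two collaborators re-measuring the
    same planes.  Returns ``(reader1, reader2)`` arrays.
    """
    if noise_sd_mm < 0:
        raise ValueError("noise_sd_mm must be >= 0")
    x = np.asarray(measurements, dtype=float)
    rng = np.random.default_rng(seed)
    r1 = x + rng.normal(0.0, noise_sd_mm, size=x.shape)
    r2 = x + rng.normal(0.0, noise_sd_mm, size=x.shape)
    return r1, r2
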