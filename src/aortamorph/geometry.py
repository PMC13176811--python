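"""Centerline extraction and perpendicular cross-section measurement.

Given a binary lumen mask (NIfTI, world coordinates in mm from the affine)
and the two anatomical landmarks delimiting the ascending aorta — the
sinotubular junction (STJ) and the brachiocephalic trunk (BT) — this module

1. extracts a smooth, arc-length-parameterised centerline hugging the lumen
   center (distance-transform-weighted minimum-cost path, spline-smoothed,
   resampled at 0.5 mm), and
2. measures cross-sections cut perpendicular to the centerline at arbitrary
   arc-length positions: maximal diameter ``d_max`` (maximal Feret diameter
   of the section contour), minimal diameter ``d_min`` (minimal caliper
   width) and area (shoelace on the subvoxel contour).

For an elliptical section the Feret diameter and caliper width coincide
with the ellipse major and minor axes, matching how clinical workstations
report Dmax/Dmin on the "diameter diagram".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d, splev, splprep
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure
from skimage.graph import route_through_array

__all__ = [
    "Centerline",
    "PlaneMeasurement",
    "DisconnectedMaskError",
    "extract_centerline",
    "measure_plane",
]


class DisconnectedMaskError(ValueError):
    """The mask is not a single connected tube between the landmarks."""


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D polyline (mm), STJ end first, with arc-length parameterisation."""

    points: np.ndarray  # (n, 3) world mm
    cumulative_arclength: np.ndarray  # (n,) mm, starts at 0
    tangent: np.ndarray  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        s = self.cumulative_arclength
        if s[0] != 0.0 or np.any(np.diff(s) <= 0):
            raise ValueError("cumulative_arclength must start at 0 and strictly increase")
        norms = np.linalg.norm(self.tangent, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("tangents must be unit-norm")

    @property
    def total_length(self) -> float:
        return float(self.cumulative_arclength[-1])

    def at(self, s_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated point and unit tangent at arc length ``s_mm``."""
        if not 0.0 <= s_mm <= self.total_length + 1e-9:
            raise ValueError(f"arc length {s_mm} outside [0, {self.total_length}]")
        p = interp1d(self.cumulative_arclength, self.points, axis=0)(s_mm)
        t = interp1d(self.cumulative_arclength, self.tangent, axis=0)(s_mm)
        return np.asarray(p), np.asarray(t) / np.linalg.norm(t)


def _world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(pts)
    return (inv[:3, :3] @ pts.T + inv[:3, 3:4]).T


def _voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(ijk)
    return (affine[:3, :3] @ ijk.T + affine[:3, 3:4]).T


def _section_centroid(data, inv_affine, origin, normal, half_extent_mm=27.0,
                      grid_mm=1.0):
    """Centroid of the perpendicular lumen section containing ``origin``."""
    u, v = _plane_basis(normal)
    g = np.arange(-half_extent_mm, half_extent_mm + grid_mm / 2, grid_mm)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    world = origin[None, :] + uu.ravel()[:, None] * u + vv.ravel()[:, None] * v
    ijk = inv_affine[:3, :3] @ world.T + inv_affine[:3, 3:4]
    field = ndimage.map_coordinates(data, ijk, order=1, mode="constant",
                                    cval=0.0).reshape(uu.shape)
    binary = field >= 0.5
    if not binary.any():
        return origin
    labels, _ = ndimage.label(binary)
    ci = len(g) // 2
    lab = labels[ci, ci]
    if lab == 0:
        fg = np.argwhere(binary)
        lab = labels[tuple(fg[np.argmin(((fg - [ci, ci]) ** 2).sum(1))])]
    sel = labels == lab
    cu = float(uu[sel].mean())
    cv = float(vv[sel].mean())
    return origin + cu * u + cv * v


def extract_centerline(mask_img, stj, bt, step_mm: float = 0.5,
                       refine_iters: int = 10) -> Centerline:
    """Extract the STJ->BT centerline from a binary tubular mask.

    The per-voxel traversal cost is ``1 / (1 + dist^2)`` with ``dist`` the
    interior Euclidean distance to the lumen surface, so the minimum-cost
    path runs along the lumen center.  Because a least-cost path still cuts
    curves slightly toward the inner bend, the path is then refined: points
    are moved to the centroid of their perpendicular lumen cross-section
    (``refine_iters`` passes), which recenters the curve to sub-voxel
    accuracy.  The refined path is smoothed with a cubic smoothing spline
    (factor reduced until the maximum deviation from the refined path stays
    below one voxel), endpoints pinned to the landmark-nearest path voxels,
    and resampled at ``step_mm``.

    Raises
    ------
    DisconnectedMaskError
        if the landmarks fall in different connected components.
    ValueError
        if a landmark lies more than ~2 voxels outside the mask.
    """
    mask = mask_img.get_fdata(dtype=np.float32) > 0.5
    affine = mask_img.affine
    spacing = np.asarray(mask_img.header.get_zooms()[:3], float)
    vox = float(np.mean(spacing))

    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    fg = np.argwhere(mask)
    fg_world = _voxel_to_world(affine, fg)

    ends = []
    for name, lm in (("stj", stj), ("bt", bt)):
        d = np.linalg.norm(fg_world - np.asarray(lm, float), axis=1)
        j = int(np.argmin(d))
        if d[j] > 2.0 * vox + 1e-6:
            raise ValueError(
                f"landmark {name!r} at {np.asarray(lm).tolist()} is {d[j]:.2f} mm "
                f"from the mask (tolerance {2.0 * vox:.2f} mm)"
            )
        ends.append(tuple(fg[j]))
    lab_a, lab_b = labels[ends[0]], labels[ends[1]]
    if lab_a != lab_b:
        raise DisconnectedMaskError(
            f"mask has {n_comp} connected components; STJ lies in component "
            f"{lab_a} but BT lies in component {lab_b}"
        )

    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    cost = np.full(mask.shape, np.inf)
    cost[mask] = 1.0 / (1.0 + dist[mask] ** 2)
    path_idx, _ = route_through_array(cost, ends[0], ends[1], fully_connected=True,
                                      geometric=True)
    raw = _voxel_to_world(affine, np.asarray(path_idx, float))

    # drop consecutive duplicates (should not occur, but keeps splprep happy)
    keep = np.r_[True, np.linalg.norm(np.diff(raw, axis=0), axis=1) > 1e-9]
    raw = raw[keep]
    # snap the path ends to the supplied landmarks (already verified to lie
    # within tolerance of the mask); the path's own ends sit at voxel centers
    # and would bias the arc length short by up to half a voxel per end
    raw[0] = np.asarray(stj, float)
    raw[-1] = np.asarray(bt, float)

    data = mask.astype(np.float32)
    inv = np.linalg.inv(affine)
    pts, _, tang = _fit_resample(raw, vox, step_mm=2.0)
    # trust-region damping: oblique early cuts can throw the section centroid
    # far off-axis, so clamp per-iteration moves and let the loop settle;
    # stop (reverting) if an iteration starts to diverge
    max_move = 1.0 * vox
    prev_mean = np.inf
    for _ in range(refine_iters):
        new = [pts[0]]
        moves = []
        for i in range(1, len(pts) - 1):
            c = _section_centroid(data, inv, pts[i], tang[i])
            delta = c - pts[i]
            norm = np.linalg.norm(delta)
            moves.append(norm)
            if norm > max_move:
                delta *= max_move / norm
            new.append(pts[i] + delta)
        new.append(pts[-1])
        mean_move = float(np.mean(moves)) if moves else 0.0
        if mean_move > 1.5 * prev_mean:
            break  # diverging: keep the previous, better-centred curve
        prev_mean = mean_move
        pts, _, tang = _fit_resample(np.asarray(new), vox, step_mm=2.0)
        if mean_move < 0.05 * vox:
            break
    pts, s_final, tang = _fit_resample(pts, vox, step_mm=step_mm)
    return Centerline(points=pts, cumulative_arclength=s_final, tangent=tang)


def _fit_resample(points: np.ndarray, vox: float, step_mm: float):
    """Smoothing-spline fit with endpoint pinning and arc-length resampling.

    The smoothing factor is halved until the fitted curve deviates from the
    input polyline by at most one voxel.
    """
    w = np.ones(len(points))
    w[0] = w[-1] = 1e4  # pin endpoints (landmark-nearest path voxels)
    k = min(3, len(points) - 1)
    smooth = len(points) * vox**2 * 16.0
    tck = None
    for _ in range(40):
        tck, u = splprep(points.T, w=w, s=smooth, k=k)
        fitted = np.column_stack(splev(u, tck))
        dev = np.linalg.norm(fitted - points, axis=1).max()
        if dev <= vox:
            break
        smooth /= 2.0
    uu = np.linspace(0.0, 1.0, max(8 * len(points), 1024))
    dense = np.column_stack(splev(uu, tck))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.r_[0.0, np.cumsum(seg)]
    total = arclen[-1]
    n_out = int(np.ceil(total / step_mm)) + 1
    s_out = np.linspace(0.0, total, n_out)
    pts = interp1d(arclen, dense, axis=0)(s_out)
    seg2 = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_final = np.r_[0.0, np.cumsum(seg2)]
    tang = np.gradient(pts, s_out, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, s_final, tang


@dataclass(frozen=True)
class PlaneMeasurement:
    """One perpendicular cross-section: diameters, area and contour."""

    arclength_mm: float
    origin: np.ndarray  # (3,) world mm
    normal: np.ndarray  # (3,) unit vector
    d_max: float  # mm, maximal Feret diameter
    d_min: float  # mm, minimal caliper width
    area: float  # mm^2
    contour: np.ndarray  # (k, 2) mm in the plane frame, closed

    def __post_init__(self) -> None:
        if not self.d_max >= self.d_min > 0:
            raise ValueError("require d_max >= d_min > 0")
        if not 0 < self.area <= (np.pi / 4) * self.d_max**2 * (1 + 1e-6):
            raise ValueError("area must be positive and <= pi/4 * d_max^2")


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def _feret_and_width(points2d: np.ndarray) -> tuple[float, float]:
    """Maximal Feret diameter and minimal caliper width of a 2D point set."""
    hull = ConvexHull(points2d)
    hp = points2d[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    feret = float(np.sqrt((diff**2).sum(-1)).max())
    # rotating calipers: the minimal width is attained perpendicular to a hull edge
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    edges = edges[lengths > 1e-12] / lengths[lengths > 1e-12, None]
    normals = np.column_stack([-edges[:, 1], edges[:, 0]])
    proj = normals @ hp.T  # (n_edges, n_pts)
    width = float((proj.max(axis=1) - proj.min(axis=1)).min())
    return feret, width


def _shoelace(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _point_in_polygon(poly: np.ndarray, pt: np.ndarray) -> bool:
    x, y = pt
    px, py = poly[:, 0], poly[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    cross = (py > y) != (qy > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xin = px + (y - py) * (qx - px) / (qy - py)
    return bool(np.count_nonzero(cross & (x < xin)) % 2)


# Field smoothing (in grid pixels) and contour low-pass (Fourier harmonics
# kept) suppress the voxelisation ripple of the interpolated 0.5-level set,
# which otherwise biases the Feret diameter up and the caliper width down.
_FIELD_SIGMA_PX = 1.0
_CONTOUR_HARMONICS = 8
_CONTOUR_SAMPLES = 512
# Planes closer than this (in voxels) to a tube cap are measured by linear
# extrapolation from two interior planes, since the trilinear field decays
# across the cap and would truncate the section.
_CAP_MARGIN_VOX = 1.25
_EXTRAP_STEP_MM = 2.5


def _fourier_smooth_contour(cm: np.ndarray, harmonics: int) -> np.ndarray:
    z = cm[:, 0] + 1j * cm[:, 1]
    d = np.abs(np.diff(z, append=z[:1]))
    t = np.r_[0.0, np.cumsum(d)][:-1]
    if t[-1] + d[-1] <= 0:
        return cm
    t = t / (t[-1] + d[-1])
    tu = np.linspace(0.0, 1.0, _CONTOUR_SAMPLES, endpoint=False)
    zu = np.interp(tu, t, z.real, period=1.0) + 1j * np.interp(tu, t, z.imag, period=1.0)
    F = np.fft.fft(zu)
    F[harmonics + 1:-harmonics] = 0.0
    zs = np.fft.ifft(F)
    return np.column_stack([zs.real, zs.imag])


def measure_plane(
    mask_img,
    centerline: Centerline,
    s_mm: float,
    grid_mm: float = 0.25,
    half_extent_mm: float = 32.0,
    normal: np.ndarray | None = None,
) -> PlaneMeasurement:
    """Measure the cross-section perpendicular to the centerline at ``s_mm``.

    The mask is resampled with trilinear interpolation on a ``grid_mm`` 2D
    grid in the cutting plane; the connected region containing the
    centerline point is kept and its subvoxel 0.5-level contour yields
    ``d_max`` (max Feret), ``d_min`` (min caliper width) and the shoelace
    area.  Planes at or next to the STJ/BT caps are obtained by linear
    extrapolation from two interior planes.  ``normal`` overrides the
    tangent direction (used by oblique-cut sanity checks).
    """
    vox = float(np.mean(mask_img.header.get_zooms()[:3]))
    margin = _CAP_MARGIN_VOX * vox
    L = centerline.total_length
    if normal is None and (s_mm < margin or s_mm > L - margin):
        s1 = margin if s_mm < margin else L - margin
        s2 = s1 + _EXTRAP_STEP_MM if s_mm < margin else s1 - _EXTRAP_STEP_MM
        m1 = measure_plane(mask_img, centerline, s1, grid_mm, half_extent_mm)
        m2 = measure_plane(mask_img, centerline, s2, grid_mm, half_extent_mm)
        t = (s_mm - s1) / (s2 - s1)
        lerp = lambda a, b: float(a + t * (b - a))
        origin, tang = centerline.at(s_mm)
        return PlaneMeasurement(
            arclength_mm=float(s_mm),
            origin=np.asarray(origin, float),
            normal=np.asarray(tang, float),
            d_max=lerp(m1.d_max, m2.d_max),
            d_min=lerp(m1.d_min, m2.d_min),
            area=lerp(m1.area, m2.area),
            contour=m1.contour,
        )

    origin, tang = centerline.at(s_mm)
    n = np.asarray(normal, float) if normal is not None else tang
    n = n / np.linalg.norm(n)
    u, v = _plane_basis(n)

    data = mask_img.get_fdata(dtype=np.float32)  # cached by nibabel across calls
    inv = np.linalg.inv(mask_img.affine)

    extent = half_extent_mm
    for attempt in range(2):
        coords_1d = np.arange(-extent, extent + grid_mm / 2, grid_mm)
        uu, vv = np.meshgrid(coords_1d, coords_1d, indexing="ij")
        world = origin[None, :] + uu.ravel()[:, None] * u + vv.ravel()[:, None] * v
        ijk = (inv[:3, :3] @ world.T + inv[:3, 3:4])
        vals = ndimage.map_coordinates(data, ijk, order=1, mode="constant", cval=0.0)
        field = ndimage.gaussian_filter(vals.reshape(uu.shape), _FIELD_SIGMA_PX)

        binary = field >= 0.5
        if not binary.any():
            raise ValueError(f"plane at s={s_mm:.1f} mm misses the lumen")
        labels, _ = ndimage.label(binary)
        ci = len(coords_1d) // 2
        center_label = labels[ci, ci]
        if center_label == 0:
            # centerline point may sit between grid nodes; use nearest foreground
            fg = np.argwhere(binary)
            j = np.argmin(((fg - [ci, ci]) ** 2).sum(1))
            center_label = labels[tuple(fg[j])]
        keep = labels == center_label
        border_touch = keep[0, :].any() or keep[-1, :].any() or keep[:, 0].any() or keep[:, -1].any()
        if border_touch:
            if attempt == 0:
                extent *= 1.6
                continue
            raise ValueError(f"section at s={s_mm:.1f} mm exceeds the sampling grid")
        break

    field_sel = np.where(keep, field, 0.0)
    contours = skmeasure.find_contours(field_sel, 0.5)
    if not contours:
        raise ValueError(f"no contour found at s={s_mm:.1f} mm")
    center_uv = np.array([0.0, 0.0])
    to_mm = lambda c: np.column_stack([coords_1d[0] + c[:, 0] * grid_mm,
                                       coords_1d[0] + c[:, 1] * grid_mm])
    chosen = None
    for c in sorted(contours, key=len, reverse=True):
        cm = to_mm(c)
        if _point_in_polygon(cm, center_uv):
            chosen = cm
            break
    if chosen is None:
        chosen = to_mm(max(contours, key=len))
    chosen = _fourier_smooth_contour(chosen, _CONTOUR_HARMONICS)

    d_max, d_min = _feret_and_width(chosen)
    area = _shoelace(chosen)
    return PlaneMeasurement(
        arclength_mm=float(s_mm),
        origin=np.asarray(origin, float),
        normal=n,
        d_max=d_max,
        d_min=d_min,
        area=area,
        contour=chosen,
    )
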