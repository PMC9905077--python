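"""Cylindrical cochlear coordinate system and angular/linear dimension conventions.

The frame follows the clinical consensus convention: the rotation axis runs
through the modiolus, the rotation (basal) plane through the basal turn, and
the 0° reference points from the axis toward the center of the round window
membrane.  Angles increase from base to apex for both ears (a handedness
flag absorbs the mirror symmetry), and unwrap beyond 360° across turns —
second-turn positions read 360–720° and so on.

Unwrapping is anchored to the spiral centerline: a reference path is marched
from the round window outward, and any point's turn index is resolved by
comparing its axial height with the centerline height at the candidate
angles.  Per-voxel ``atan2`` alone cannot distinguish turns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .core import LabelVolume, UM_PER_MM

__all__ = [
    "CochlearFrame",
    "SpiralReference",
    "fit_frame",
    "build_reference",
    "angular_position",
    "count_turns",
    "angular_range",
    "measure_cochlea_dimensions",
]

#: structures forming the spiral lumen complex used for axis/centerline fits
_LUMEN_NAMES = (
    "scala_tympani",
    "scala_vestibuli",
    "scala_media",
    "fluid",
    "electrode",
    "rwm",
    "bm",
    "rm",
    "cpb_ooc",
    "osl",
    "sl",
    "ssl",
    "rc",
)

_FLUID_NAMES = ("scala_tympani", "scala_vestibuli", "scala_media", "fluid")


@dataclass
class CochlearFrame:
    """Cochlear cylindrical frame: modiolar axis, basal plane and 0° reference."""

    axis_point_mm: np.ndarray  # (x, y, z), a point on the axis in the basal plane
    axis_dir: np.ndarray  # unit vector, base -> apex
    zero_dir: np.ndarray  # unit vector in the basal plane toward the RWM center
    handedness: str  # 'left' or 'right': sense of increasing angle base->apex

    def __post_init__(self) -> None:
        self.axis_point_mm = np.asarray(self.axis_point_mm, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        self.zero_dir = np.asarray(self.zero_dir, dtype=float)
        self.axis_dir = self.axis_dir / np.linalg.norm(self.axis_dir)
        # re-orthogonalize zero_dir against the axis
        z = self.zero_dir - (self.zero_dir @ self.axis_dir) * self.axis_dir
        self.zero_dir = z / np.linalg.norm(z)
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def e2(self) -> np.ndarray:
        """In-plane unit vector at +90° (in the handedness sense)."""
        s = 1.0 if self.handedness == "left" else -1.0
        return s * np.cross(self.axis_dir, self.zero_dir)

    def to_dict(self) -> dict:
        return {
            "axis_point_mm": self.axis_point_mm.tolist(),
            "axis_dir": self.axis_dir.tolist(),
            "zero_dir": self.zero_dir.tolist(),
            "handedness": self.handedness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CochlearFrame":
        return cls(
            np.array(d["axis_point_mm"]),
            np.array(d["axis_dir"]),
            np.array(d["zero_dir"]),
            d["handedness"],
        )


@dataclass
class SpiralReference:
    """Centerline samples used to unwrap angles across turns."""

    theta_deg: np.ndarray  # strictly increasing unwrapped angle
    z_mm: np.ndarray  # axial coordinate at each theta
    rho_mm: np.ndarray  # in-plane radius at each theta

    @property
    def theta_max(self) -> float:
        return float(self.theta_deg[-1])


# ---------------------------------------------------------------------------
# helpers


def _points_mm(mask: np.ndarray, voxel_size_um: float) -> np.ndarray:
    """(N, 3) world coordinates (x, y, z) in mm of True voxels."""
    idx = np.argwhere(mask)  # (z, y, x)
    vs = voxel_size_um / UM_PER_MM
    return (idx[:, ::-1] + 0.5) * vs


def _mask_any(labels: LabelVolume, names) -> np.ndarray:
    ids = [labels.names[n] for n in names if n in labels.names]
    if not ids:
        raise ValueError(f"labels contain none of {names}")
    return np.isin(labels.data, ids)


def _skeleton_path(mask: np.ndarray, voxel_size_um: float, seed_mm: np.ndarray) -> np.ndarray:
    """Ordered centerline points (mm) from the end nearest ``seed_mm`` outward.

    Skeletonizes the mask, then follows the weighted geodesic from the
    skeleton voxel nearest the seed to the farthest reachable voxel.
    """
    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    if len(pts) < 2:
        raise ValueError("mask too small to extract a centerline")
    vs = voxel_size_um / UM_PER_MM
    # adjacency over 26-neighborhood
    key = {tuple(p): i for i, p in enumerate(map(tuple, pts))}
    rows, cols, wts = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    for off in offsets:
        shifted = pts + off
        w = float(np.linalg.norm(off)) * vs
        for i, q in enumerate(map(tuple, shifted)):
            j = key.get(q)
            if j is not None:
                rows.append(i)
                cols.append(j)
                wts.append(w)
    n = len(pts)
    g = sparse.csr_matrix((wts, (rows, cols)), shape=(n, n))
    g = g + g.T
    world = (pts[:, ::-1] + 0.5) * vs  # (x, y, z) mm
    start = int(np.argmin(np.linalg.norm(world - seed_mm, axis=1)))
    dist, pred = dijkstra(g, indices=start, return_predecessors=True)
    dist[np.isinf(dist)] = -1
    end = int(np.argmax(dist))
    path = [end]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    path.reverse()
    return world[path]


def _raw_azimuth(points_mm: np.ndarray, frame: CochlearFrame) -> np.ndarray:
    d = np.atleast_2d(points_mm) - frame.axis_point_mm
    u1 = d @ frame.zero_dir
    u2 = d @ frame.e2
    rho = np.hypot(u1, u2)
    if np.any(rho < 1e-9):
        raise ValueError("undefined azimuth: point on the modiolar axis")
    return np.degrees(np.arctan2(u2, u1)), rho, d @ frame.axis_dir


def _unwrap_path(alpha_deg: np.ndarray) -> np.ndarray:
    """Cumulative unwrapping of azimuths ordered along the spiral."""
    a0 = alpha_deg[0]
    if a0 > 180.0:  # basal end may sit just before the 0° reference
        a0 -= 360.0
    d = np.diff(alpha_deg)
    d = (d + 180.0) % 360.0 - 180.0
    return np.concatenate([[a0], a0 + np.cumsum(d)])


# ---------------------------------------------------------------------------
# frame fitting


def fit_frame(labels: LabelVolume) -> CochlearFrame:
    """Fit the cochlear frame from a label volume.

    The modiolar axis is the least-squares normal of the spiral lumen point
    cloud; the basal plane passes through the first-turn centerline segment;
    the 0° direction points toward the RWM centroid; the handedness is read
    off the rotation sense of the centerline marched from the RWM outward.
    """
    if "rwm" not in labels.names or not (labels.data == labels.names["rwm"]).any():
        raise ValueError("labels must contain a non-empty 'rwm' structure")
    lumen = _mask_any(labels, _LUMEN_NAMES)
    if not lumen.any():
        raise ValueError("labels contain no spiral lumen structures")

    rwm_ctr = _points_mm(labels.data == labels.names["rwm"], labels.voxel_size_um).mean(axis=0)

    path = _skeleton_path(lumen, labels.voxel_size_um, rwm_ctr)
    # initial axis: plane normal of the centerline (well-conditioned even for
    # sub-turn arcs, unlike the voxel cloud with its tube-thickness spread)
    ctr = path.mean(axis=0)
    _, evecs = np.linalg.eigh(np.cov((path - ctr).T))
    axis = evecs[:, 0]
    # orient base -> apex (apex = far end of the path)
    if (path[-1] - path[0]) @ axis < 0:
        axis = -axis

    # The raw plane normal is biased by the helical rise.  Refine by fitting
    # a helix — linear axial rise and linearly decaying radius around a
    # tiltable axis — to the centerline directly; this stays well conditioned
    # from sub-turn arcs up to full multi-turn spirals.
    def _basis(ax):
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(tmp @ ax) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        b1 = tmp - (tmp @ ax) * ax
        b1 /= np.linalg.norm(b1)
        return b1, np.cross(ax, b1)

    theta = None
    for _ in range(3):
        e1, e2 = _basis(axis)
        d = path - ctr
        alpha = np.degrees(np.arctan2(d @ e2, d @ e1))
        theta = _unwrap_path(alpha)
        theta = theta - theta[0]
        z0 = d @ axis
        rho0 = np.hypot(d @ e1, d @ e2)

        def resid(p, theta=theta):
            ax = axis + p[2] * e1 + p[3] * e2
            ax = ax / np.linalg.norm(ax)
            b1, b2 = _basis(ax)
            dd = path - (ctr + p[0] * e1 + p[1] * e2)
            z = dd @ ax
            rho = np.hypot(dd @ b1, dd @ b2)
            return np.concatenate([z - (p[4] + p[5] * theta), rho - (p[6] + p[7] * theta)])

        x0 = [
            0.0, 0.0, 0.0, 0.0,
            float(z0.mean()),
            float((z0[-1] - z0[0]) / max(theta[-1] - theta[0], 1e-9)),
            float(rho0.mean()), 0.0,
        ]
        fit = least_squares(resid, x0=x0, method="lm")
        new_axis = axis + fit.x[2] * e1 + fit.x[3] * e2
        new_axis /= np.linalg.norm(new_axis)
        ctr = ctr + fit.x[0] * e1 + fit.x[1] * e2
        done = abs(new_axis @ axis) > 1.0 - 1e-12
        axis = new_axis
        if done:
            break
    if (path[-1] - path[0]) @ axis < 0:
        axis = -axis
        theta = -theta
    handedness = "left" if theta[-1] > theta[0] else "right"
    e1, e2 = _basis(axis)

    # Refine the in-plane axis position: fit a decaying spiral with an
    # optional in-plane elongation, ρ(θ) = (a + bθ)(1 + e·cos²(α − ψ)),
    # over the whole centerline.  Re-unwrap after each center update.
    center = ctr
    for _ in range(3):
        d = path - center
        alpha = np.degrees(np.arctan2(d @ e2, d @ e1))
        th = np.abs(_unwrap_path(alpha))
        rho = np.hypot(d @ e1, d @ e2)

        def resid(p, th=th, alpha=alpha):
            dd = path - (center + p[0] * e1 + p[1] * e2)
            r = np.hypot(dd @ e1, dd @ e2)
            model = (p[2] + p[3] * th) * (
                1.0 + p[4] * np.cos(np.radians(alpha) - p[5]) ** 2
            )
            return r - model

        fit = least_squares(
            resid, x0=[0.0, 0.0, float(rho.mean()), -1e-4, 0.0, 0.0], method="lm"
        )
        center = center + fit.x[0] * e1 + fit.x[1] * e2
        if np.hypot(fit.x[0], fit.x[1]) < 1e-4:
            break

    # Second center refinement on the fluid tube itself: per-angular-bin
    # centroids of the fluid voxels are symmetric around the true centerline
    # and pin the axis position to a fraction of a voxel, which matters for
    # angular accuracy at the small apical radius.
    try:
        fluid = _mask_any(labels, _FLUID_NAMES)
        f_pts = _points_mm(fluid, labels.voxel_size_um)
        f_pts = f_pts[:: max(1, len(f_pts) // 100_000)]
        zero0 = rwm_ctr - center
        zero0 = zero0 - (zero0 @ axis) * axis
        zero0 /= np.linalg.norm(zero0)
        tmp_frame = CochlearFrame(center, axis, zero0, handedness)
        ref = build_reference(labels, tmp_frame)
        th_f = angular_position(f_pts, tmp_frame, ref)
        bins = np.round(th_f / 10.0).astype(int)
        cent, th_c = [], []
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 20:
                continue
            # median coordinates: robust against stray turn misassignments
            cent.append(np.median(f_pts[sel], axis=0))
            th_c.append(float(np.median(th_f[sel])))
        cent = np.asarray(cent)
        th_c = np.asarray(th_c)
        # keep only bins inside the trustworthy centerline span
        keep = (th_c > ref.theta_deg[0] + 10.0) & (th_c < ref.theta_max - 10.0)
        cent, th_c = cent[keep], th_c[keep]

        def resid2(p):
            dd = cent - (center + p[0] * e1 + p[1] * e2)
            r = np.hypot(dd @ e1, dd @ e2)
            a_c = np.degrees(np.arctan2(dd @ e2, dd @ e1))
            model = (p[2] + p[3] * th_c) * (1.0 + p[4] * np.cos(np.radians(a_c) - p[5]) ** 2)
            return r - model

        rho_c = np.hypot((cent - center) @ e1, (cent - center) @ e2)
        fit2 = least_squares(
            resid2, x0=[0.0, 0.0, float(rho_c.mean()), -1e-4, 0.0, 0.0], method="lm"
        )
        center = center + fit2.x[0] * e1 + fit2.x[1] * e2
    except (ValueError, KeyError):
        pass  # no fluid labels: keep the skeleton-based center

    d = path - center
    basal_theta = np.abs(_unwrap_path(np.degrees(np.arctan2(d @ e2, d @ e1))))
    pb = path[basal_theta <= min(360.0, basal_theta[-1])]
    z_basal = float(((pb - center) @ axis).mean())
    axis_point = center + z_basal * axis

    zero = rwm_ctr - axis_point
    zero = zero - (zero @ axis) * axis
    zero /= np.linalg.norm(zero)
    return CochlearFrame(axis_point, axis, zero, handedness)


def _reference_tables(ref: SpiralReference):
    """Interpolators θ → (z, ρ) with linear extrapolation beyond the span."""
    th_ref, z_ref, rho_ref = ref.theta_deg, ref.z_mm, ref.rho_mm
    z_slope = np.polyfit(th_ref, z_ref, 1)[0]
    rho_slope = np.polyfit(th_ref, rho_ref, 1)[0]

    def z_at(th):
        v = np.interp(th, th_ref, z_ref)
        v = np.where(th < th_ref[0], z_ref[0] + z_slope * (th - th_ref[0]), v)
        v = np.where(th > th_ref[-1], z_ref[-1] + z_slope * (th - th_ref[-1]), v)
        return v

    def rho_at(th):
        v = np.interp(th, th_ref, rho_ref)
        v = np.where(th < th_ref[0], rho_ref[0] + rho_slope * (th - th_ref[0]), v)
        v = np.where(th > th_ref[-1], rho_ref[-1] + rho_slope * (th - th_ref[-1]), v)
        return v

    return z_at, rho_at


def _unwrap_points(alpha, z, rho, ref: SpiralReference):
    """Pick, per point, the turn whose cross-section centroid is nearest.

    The cost is the in-plane cross-section distance hypot(Δz, Δρ) — the same
    rule a tube of the reference spiral would use to claim a voxel.
    """
    z_at, rho_at = _reference_tables(ref)
    k_max = int(np.ceil((ref.theta_max + 90.0) / 360.0))
    cands, costs = [], []
    for k in range(-1, k_max + 1):
        th = alpha + 360.0 * k
        cost = np.hypot(z - z_at(th), rho - rho_at(th))
        outside = (th < -90.0) | (th > ref.theta_max + 90.0)
        cands.append(th)
        costs.append(np.where(outside, np.inf, cost))
    cands = np.stack(cands)
    costs = np.stack(costs)
    best = np.argmin(costs, axis=0)
    return cands[best, np.arange(alpha.size)]


def build_reference(
    labels: LabelVolume, frame: CochlearFrame, bin_deg: float = 10.0
) -> SpiralReference:
    """Tabulate the spiral's cross-section centroid path θ → (z, ρ).

    A skeleton centerline marched from the RWM outward provides a provisional
    unwrapping; the final table is the per-angular-bin median height and
    radius of all lumen-complex voxels, which centers the reference on the
    cross-section rather than on the skeleton's (radius-biased) medial curve.
    """
    lumen = _mask_any(labels, _LUMEN_NAMES)
    rwm_ctr = _points_mm(labels.data == labels.names["rwm"], labels.voxel_size_um).mean(axis=0)
    path = _skeleton_path(lumen, labels.voxel_size_um, rwm_ctr)
    alpha, rho, z = _raw_azimuth(path, frame)
    theta = _unwrap_path(alpha)
    order = np.argsort(theta)
    theta, z, rho = theta[order], z[order], rho[order]
    keep = np.concatenate([[True], np.diff(theta) > 1e-9])
    ref = SpiralReference(theta[keep], z[keep], rho[keep])

    # the skeleton's angular span is trustworthy (it can only fall short by
    # end erosion); anything assigned far outside it is a misassignment
    span = (float(ref.theta_deg[0]) - 40.0, float(ref.theta_max) + 40.0)

    pts = _points_mm(lumen, labels.voxel_size_um)
    pts = pts[:: max(1, len(pts) // 200_000)]
    a, r, zz = _raw_azimuth(pts, frame)
    for _ in range(2):
        th = _unwrap_points(a % 360.0, zz, r, ref)
        ok = (th >= span[0]) & (th <= span[1])
        lo = min(0.0, float(th[ok].min()))
        nbin = max(int(np.ceil((th[ok].max() - lo) / bin_deg)), 2)
        idx = np.clip(((th - lo) / bin_deg).astype(int), 0, nbin - 1)
        centers, med_z, med_rho = [], [], []
        for b in range(nbin):
            sel = ok & (idx == b)
            if sel.sum() < 10:
                continue
            centers.append(lo + (b + 0.5) * bin_deg)
            med_z.append(np.median(zz[sel]))
            med_rho.append(np.median(r[sel]))
        centers = np.array(centers)
        med_z = np.array(med_z)
        med_rho = np.array(med_rho)
        if centers.size >= 4:
            # continuity filter: bins fed by turn-misassigned voxels sit about
            # one pitch off the spiral's linear axial rise — drop them
            slope, icpt = np.polyfit(centers, med_z, 1)
            resid = med_z - (slope * centers + icpt)
            tol = max(0.25 * abs(slope) * 360.0, 10 * np.median(np.abs(resid)) + 1e-6)
            good = np.abs(resid) <= tol
            centers, med_z, med_rho = centers[good], med_z[good], med_rho[good]
        ref = SpiralReference(centers, med_z, med_rho)
    return ref


# ---------------------------------------------------------------------------
# angular measurements


def angular_position(
    points_mm: np.ndarray,
    frame: CochlearFrame,
    reference: SpiralReference | None = None,
) -> np.ndarray:
    """Unwrapped angular position (deg) of points about the modiolar axis.

    Without a reference the principal azimuth in [0, 360) is returned (the
    RWM centroid reads ≈ 0°).  With a centerline reference, each point is
    assigned to the turn whose centerline height best matches its own, so
    second-turn points report 360–720° and so on.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    alpha, rho, z = _raw_azimuth(points_mm, frame)
    if reference is None:
        # principal value in (-180, 180]: the RWM centroid reads ~0°
        return (alpha + 180.0) % 360.0 - 180.0
    return _unwrap_points(alpha % 360.0, z, rho, reference)


def count_turns(
    labels: LabelVolume,
    frame: CochlearFrame,
    reference: SpiralReference | None = None,
) -> float:
    """Number of cochlear turns: maximal unwrapped lumen angle / 360, to 0.1."""
    reference = reference or build_reference(labels, frame)
    fluid = _mask_any(labels, _FLUID_NAMES)
    pts = _points_mm(fluid, labels.voxel_size_um)
    theta = angular_position(pts, frame, reference)
    return round(float(theta.max()) / 360.0, 1)


def angular_range(
    labels: LabelVolume,
    structure: str,
    frame: CochlearFrame,
    reference: SpiralReference | None = None,
) -> tuple[float, float]:
    """(start, end) unwrapped angular extent of a structure's voxels."""
    mask = labels.mask(structure)
    reference = reference or build_reference(labels, frame)
    pts = _points_mm(mask, labels.voxel_size_um)
    theta = angular_position(pts, frame, reference)
    return float(max(theta.min(), 0.0)), float(theta.max())


def measure_cochlea_dimensions(labels: LabelVolume, frame: CochlearFrame) -> dict:
    """Cochlear length, width and height (mm).

    Length: the largest basal-plane extent along the axis→RWM line; width:
    the in-plane perpendicular extent; height: the extent along the modiolar
    axis.  Reference-material labels are excluded.  Extents are inclusive
    (max − min plus one voxel).
    """
    exclude = {labels.names.get("parafilm"), 0}
    mask = ~np.isin(labels.data, [e for e in exclude if e is not None])
    if not mask.any():
        raise ValueError("empty label volume")
    pts = _points_mm(mask, labels.voxel_size_um)
    d = pts - frame.axis_point_mm
    vs = labels.voxel_size_um / UM_PER_MM
    out = {}
    for name, e in (("length", frame.zero_dir), ("width", frame.e2), ("height", frame.axis_dir)):
        proj = d @ e
        out[name] = float(proj.max() - proj.min() + vs)
    return out
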