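"""Synthetic cochlear phantom with exact ground truth.

The phantom emulates what a stained, scanned and segmented human cochlea
provides to the analysis chain: a grey-value volume, an integer label
volume, and the cylindrical cochlear frame.  The geometry is a spiral of
``turns`` revolutions whose centerline radius decays linearly with angle
and rises at a constant axial pitch; the scalae are circular tubes around
that centerline and the membranes, laminae and canals are schematic
regions defined in the local tube cross-section.  The model keeps exactly
the quantities the analysis measures — number of turns, unwrapped angular
positions, centerline lengths, structure volumes, membrane thicknesses —
well defined and analytically known.

Units: spec lengths in µm; ground-truth outputs in mm / mm³ / degrees.
Unwrapped angle θ is 0° at the round window membrane and increases
base→apex, so a 2.8-turn cochlea spans 0–1008°.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import LabelVolume, Volume3D, UM_PER_MM

__all__ = [
    "PhantomSpec",
    "Phantom",
    "StainState",
    "Lesion",
    "LABELS",
    "FLUID_STRUCTURES",
    "SOFT_TISSUE_STRUCTURES",
    "BONE_STRUCTURES",
    "DEFAULT_ATTENUATION",
    "generate_phantom",
    "simulate_staining",
    "insert_electrode",
    "membrane_patch",
    "spec_from_dimensions",
    "calibrate_spec_to_dimensions",
    "stain_uptake",
]

# ---------------------------------------------------------------------------
# label vocabulary

LABELS: dict[str, int] = {
    "scala_tympani": 1,
    "scala_vestibuli": 2,
    "scala_media": 3,
    "rwm": 4,
    "bm": 5,
    "rm": 6,
    "cpb_ooc": 7,
    "osl": 8,
    "sl": 9,
    "ssl": 10,
    "rwa": 11,
    "rc": 12,
    "capsule": 13,
    "parafilm": 14,
    "electrode": 15,
}

FLUID_STRUCTURES = ("scala_tympani", "scala_vestibuli", "scala_media")
SOFT_TISSUE_STRUCTURES = ("rwm", "bm", "rm", "cpb_ooc", "sl", "rc")
BONE_STRUCTURES = ("osl", "ssl", "rwa", "capsule")

#: attenuation coefficients in 1/mm; ordering mirrors the contrast relations
#: of a stained scan (fluid < parafilm < stained soft tissue < porous bone <
#: cortical bone << metal).
DEFAULT_ATTENUATION: dict[str, float] = {
    "background": 0.0,
    "scala_tympani": 0.02,
    "scala_vestibuli": 0.02,
    "scala_media": 0.02,
    "rwm": 0.12,
    "bm": 0.12,
    "rm": 0.12,
    "cpb_ooc": 0.12,
    "sl": 0.12,
    "rc": 0.12,
    "osl": 0.30,
    "ssl": 0.18,
    "rwa": 0.30,
    "capsule": 0.30,
    "parafilm": 0.05,
    "electrode": 3.0,
}

FLUID_ATTENUATION = 0.02


# ---------------------------------------------------------------------------
# spec


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cochlea.  All lengths in µm, angles in deg.

    The cross-section layout lives in local tube coordinates ``(u, w)``:
    ``u`` is the radial offset from the spiral centerline (positive toward
    the outer wall), ``w`` the axial offset (positive toward the apex).
    ``cross_section_scale`` shrinks the whole cross-section uniformly, which
    lets small cochleae keep a safe inter-turn clearance.
    """

    grid_shape: tuple[int, int, int] = (192, 192, 192)  # (z, y, x)
    voxel_size: float = 35.0
    turns: float = 2.8
    basal_radius: float = 2200.0
    radius_decay: float = 0.26  # fraction of basal radius lost per turn
    ellipticity: float = 0.0  # cos²θ in-plane elongation of the spiral
    pitch: float = 1000.0  # axial rise per turn
    handedness: str = "left"

    cross_section_scale: float = 1.0
    scala_tympani_radius: float = 170.0
    scala_vestibuli_radius: float = 140.0
    scala_media_radius: float = 60.0
    st_offset: float = 280.0  # |w| of the ST center below the partition
    sv_offset: float = 330.0  # w of the SV center above the partition
    rwm_thickness: float = 120.0
    bm_thickness: float = 50.0
    rm_thickness: float = 45.0
    osl_thickness: float = 100.0
    osl_reach: float = 440.0  # inner u extent of the bony lamina
    sl_thickness: float = 150.0
    ssl_end: float = 572.0  # unwrapped angle where the SSL ridge stops
    ssl_width: float = 140.0
    ssl_height: float = 110.0
    rwa_end: float = 45.0
    rwa_thickness: float = 100.0
    rc_radius: float = 130.0
    rc_offset: float = 520.0  # radial distance of the RC center inside the lumen
    rc_start: float = 10.0
    rc_end: float = 750.0
    capsule_thickness: float = 250.0
    envelope_u: tuple[float, float] = (-680.0, 350.0)
    envelope_w: float = 460.0

    attenuation_table: dict = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    parafilm_block: bool = True
    texture_sd: float = 0.005  # 1/mm, grey-value texture noise
    seed: int = 0

    # ---- invariants ------------------------------------------------------
    def validate(self) -> None:
        if not self.turns > 0:
            raise ValueError("turns must be > 0")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.pitch <= 0 or self.basal_radius <= 0:
            raise ValueError("pitch and basal_radius must be > 0")
        if self.radius_decay * self.turns >= 0.95:
            raise ValueError("radius_decay too large: spiral radius reaches zero")
        s = self.cross_section_scale
        thin = {
            "scala_tympani": self.scala_tympani_radius * s,
            "scala_vestibuli": self.scala_vestibuli_radius * s,
            "scala_media": self.scala_media_radius * s,
            "rwm": self.rwm_thickness,
            "bm": self.bm_thickness,
            "rm": self.rm_thickness,
            "osl": self.osl_thickness * s,
            "sl": self.sl_thickness * s,
            "ssl": min(self.ssl_width, self.ssl_height) * s,
            "rwa": self.rwa_thickness * s,
            "rc": self.rc_radius * s,
            "capsule": self.capsule_thickness,
        }
        for name, size in thin.items():
            if size <= 0:
                raise ValueError(f"structure {name!r} has non-positive size")
            if size < self.voxel_size:
                raise ValueError(
                    f"structure {name!r} is thinner than one voxel "
                    f"({size:.1f} µm < {self.voxel_size:.1f} µm)"
                )
        missing = [n for n in LABELS if n not in self.attenuation_table and n != "electrode"]
        if missing:
            raise ValueError(f"attenuation_table misses labels: {missing}")
        # inter-turn clearance: consecutive turns must not collide
        if self.turns > 1:
            dz = self.pitch
            dr = self.basal_radius * self.radius_decay
            clearance = float(np.hypot(dz, dr))
            needed = 2 * (self.sv_offset + self.scala_vestibuli_radius) * s + 2 * self.voxel_size
            if clearance < needed:
                raise ValueError(
                    f"inter-turn clearance {clearance:.0f} µm < required {needed:.0f} µm; "
                    "increase pitch or reduce cross_section_scale"
                )

    @property
    def angular_extent(self) -> float:
        return self.turns * 360.0

    def spiral_radius(self, theta_deg: np.ndarray) -> np.ndarray:
        """Centerline radius (µm) at unwrapped angle θ."""
        th = np.asarray(theta_deg, dtype=float)
        base = self.basal_radius * (1.0 - self.radius_decay * th / 360.0)
        if self.ellipticity:
            base = base * (1.0 + self.ellipticity * np.cos(np.radians(th)) ** 2)
        return base

    def spiral_z(self, theta_deg: np.ndarray) -> np.ndarray:
        """Centerline axial coordinate (µm, relative to the basal plane)."""
        return self.pitch * np.asarray(theta_deg, dtype=float) / 360.0

    def centerline_arclength_mm(self, theta_end: float | None = None) -> float:
        """Analytic arc length of the spiral centerline up to ``theta_end``."""
        end = self.angular_extent if theta_end is None else float(theta_end)
        th = np.linspace(0.0, end, max(int(end * 4), 16))
        r = self.spiral_radius(th)
        dr = np.gradient(r, th)
        dz = self.pitch / 360.0
        ds = np.sqrt(dr**2 + (r * np.pi / 180.0) ** 2 + dz**2)
        return float(np.trapezoid(ds, th) / UM_PER_MM)

    def rwm_angular_thickness(self) -> float:
        """Angular span (deg) of the RWM cap at the base of the ST."""
        return float(np.degrees(self.rwm_thickness / self.spiral_radius(0.0)))


@dataclass(frozen=True)
class Lesion:
    """One electrode-insertion lesion: a structure, a type and an angular range."""

    structure: str
    kind: str  # fracture | tear | deformation | elevation | scala-vestibuli translocation
    theta_start: float
    theta_end: float

    KINDS = ("fracture", "tear", "deformation", "elevation", "scala-vestibuli translocation")


@dataclass
class StainState:
    """State of the base-to-apex staining front at a given submersion time."""

    time_h: float
    front_rate_turns_per_day: float
    front_width_deg: float
    uptake: np.ndarray  # per-voxel contrast multiplier in [0, 1]

    @property
    def front_deg(self) -> float:
        return self.front_rate_turns_per_day * (self.time_h / 24.0) * 360.0


@dataclass
class Phantom:
    """A generated cochlea: grey volume, labels, ground-truth frame and tables.

    ``theta``/``u``/``w`` are the generator's per-voxel ground-truth tube
    coordinates (NaN outside the cochlea) — the exact quantities the
    coordinate module must recover from labels alone.
    """

    spec: PhantomSpec
    grey: Volume3D
    labels: LabelVolume
    frame: "object"  # cochlect.coords.CochlearFrame (kept loose to avoid a cycle)
    truth: dict
    theta: np.ndarray
    u: np.ndarray
    w: np.ndarray
    lesion_table: pd.DataFrame | None = None

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.labels.data))
        h.update(np.ascontiguousarray(self.grey.data))
        return h.hexdigest()


# ---------------------------------------------------------------------------
# generation


def _tube_coordinates(spec: PhantomSpec):
    """Per-voxel unwrapped angle θ and cross-section offsets (u, w) in µm.

    Each voxel's azimuth admits one candidate unwrapped angle per turn;
    the candidate whose tube cross-section center is nearest wins.
    """
    nz, ny, nx = spec.grid_shape
    vs = spec.voxel_size
    z = (np.arange(nz) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    x = (np.arange(nx) + 0.5) * vs
    cx, cy = x.mean(), y.mean()
    extent = spec.angular_extent
    z0 = (z[-1] + z[0]) / 2.0 - spec.spiral_z(extent) / 2.0  # basal plane height

    Zc = (z - z0).astype(np.float32)[:, None, None]
    Yc = (y - cy).astype(np.float32)[None, :, None]
    Xc = (x - cx).astype(np.float32)[None, None, :]
    sgn = 1.0 if spec.handedness == "left" else -1.0
    rho = np.hypot(Xc, Yc)
    phi = np.degrees(np.arctan2(np.float32(sgn) * Yc, Xc + 0 * rho)) % np.float32(360.0)
    Z = Zc + 0 * rho

    n_cand = int(np.ceil(spec.turns)) + 1
    best_d = np.full(spec.grid_shape, np.inf, dtype=np.float32)
    theta = np.full(spec.grid_shape, np.nan, dtype=np.float32)
    u = np.full(spec.grid_shape, np.nan, dtype=np.float32)
    w = np.full(spec.grid_shape, np.nan, dtype=np.float32)
    # k = -1 admits the small negative-angle window occupied by the RWM cap,
    # which is centered on the 0° reference (the center of the round window)
    theta_lo = -spec.rwm_angular_thickness() / 2.0
    for k in range(-1, n_cand):
        th_k = phi + np.float32(360.0 * k)
        valid = (th_k <= extent) & (th_k >= theta_lo)
        if not valid.any():
            continue
        r_k = spec.spiral_radius(th_k).astype(np.float32)
        u_k = rho - r_k
        w_k = Z - spec.spiral_z(th_k).astype(np.float32)
        d_k = np.hypot(u_k, w_k)
        d_k = np.where(valid, d_k, np.float32(np.inf))
        better = d_k < best_d
        best_d = np.where(better, d_k, best_d)
        theta = np.where(better, th_k, theta)
        u = np.where(better, u_k, u)
        w = np.where(better, w_k, w)
    return theta, u, w, (z0, cy, cx)


def _classify(spec: PhantomSpec, theta, u, w) -> np.ndarray:
    """Assign labels from tube coordinates, highest precedence first."""
    s = spec.cross_section_scale
    lab = np.zeros(spec.grid_shape, dtype=np.uint8)
    inside = np.isfinite(theta)
    th, uu, ww = theta, u, w

    st_c = (0.0, -spec.st_offset * s)
    sv_c = (0.0, spec.sv_offset * s)
    sm_c = (90.0 * s, 140.0 * s)

    d_st = np.hypot(uu - st_c[0], ww - st_c[1])
    d_sv = np.hypot(uu - sv_c[0], ww - sv_c[1])
    d_sm = np.hypot(uu - sm_c[0], ww - sm_c[1])

    rwm_span = spec.rwm_angular_thickness()
    lumen_u_out = 170.0 * s  # outer edge of the fluid space at partition level

    regions: list[tuple[str, np.ndarray]] = []
    # membrane cap centered on the 0° reference (center of the round window)
    regions.append(("rwm", (d_st <= spec.scala_tympani_radius * s) & (np.abs(th) <= rwm_span / 2.0)))
    regions.append((
        "rwa",
        (d_st > spec.scala_tympani_radius * s)
        & (d_st <= (spec.scala_tympani_radius + spec.rwa_thickness) * s)
        & (ww >= st_c[1])
        & (th <= spec.rwa_end),
    ))
    regions.append((
        "ssl",
        (th <= spec.ssl_end)
        & (uu >= (lumen_u_out + 30.0) * s)
        & (uu <= (lumen_u_out + 30.0) * s + spec.ssl_width * s)
        & (np.abs(ww + 25.0 * s) <= spec.ssl_height * s / 2.0),
    ))
    regions.append((
        "osl",
        (uu >= -spec.osl_reach * s)
        & (uu <= 20.0 * s)
        & (np.abs(ww) <= spec.osl_thickness * s / 2.0),
    ))
    regions.append((
        "bm",
        (uu > 20.0 * s) & (uu <= lumen_u_out * s) & (np.abs(ww) <= spec.bm_thickness / 2.0),
    ))
    regions.append((
        "cpb_ooc",
        (uu > 20.0 * s)
        & (uu <= 120.0 * s)
        & (ww > spec.bm_thickness / 2.0)
        & (ww <= spec.bm_thickness / 2.0 + 90.0 * s),
    ))
    regions.append((
        "rm",
        (uu >= 10.0 * s)
        & (uu <= lumen_u_out * s)
        & (np.abs(ww - 205.0 * s) <= spec.rm_thickness / 2.0),
    ))
    regions.append((
        "rc",
        (d_sm * 0 + np.hypot(uu + spec.rc_offset * s, ww + 150.0 * s) <= spec.rc_radius * s)
        & (th >= spec.rc_start)
        & (th <= spec.rc_end),
    ))
    regions.append(("scala_tympani", d_st <= spec.scala_tympani_radius * s))
    regions.append(("scala_vestibuli", d_sv <= spec.scala_vestibuli_radius * s))
    regions.append(("scala_media", d_sm <= spec.scala_media_radius * s))
    regions.append((
        "sl",
        (uu > (lumen_u_out + 10.0) * s)
        & (uu <= (lumen_u_out + 10.0) * s + spec.sl_thickness * s)
        & (ww >= -300.0 * s)
        & (ww <= 380.0 * s),
    ))
    u_in, u_out = spec.envelope_u
    c = spec.capsule_thickness
    regions.append((
        "capsule",
        (uu >= u_in * s - c)
        & (uu <= u_out * s + c)
        & (np.abs(ww) <= spec.envelope_w * s + c),
    ))

    for name, cond in regions:
        sel = inside & cond & (lab == 0)
        lab[sel] = LABELS[name]
    return lab


def _place_parafilm(spec: PhantomSpec, lab: np.ndarray) -> None:
    """Reference foil analog: a small block near a grid corner."""
    nz, ny, nx = spec.grid_shape
    bz = max(2, nz // 16)
    by = max(2, ny // 16)
    bx = max(2, nx // 16)
    sl = (slice(nz // 2 - 2 * bz, nz // 2 + 2 * bz), slice(3, 3 + by), slice(3, 3 + bx))
    if (lab[sl] != 0).any():
        raise ValueError("parafilm reference block collides with the cochlea")
    lab[sl] = LABELS["parafilm"]


def _grey_from_labels(
    spec: PhantomSpec, lab: np.ndarray, uptake: np.ndarray | None = None
) -> Volume3D:
    """Attenuation volume from labels; soft tissues interpolate fluid→stained."""
    table = spec.attenuation_table
    lut = np.zeros(256, dtype=np.float32)
    for name, idx in LABELS.items():
        lut[idx] = table.get(name, 0.0)
    grey = lut[lab]
    if uptake is not None:
        soft = np.isin(lab, [LABELS[n] for n in SOFT_TISSUE_STRUCTURES])
        grey[soft] = FLUID_ATTENUATION + uptake[soft] * (grey[soft] - FLUID_ATTENUATION)
    if spec.texture_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.texture_sd, size=grey.shape).astype(np.float32)
        np.maximum(grey, 0.0, out=grey)
    return Volume3D(grey.astype(np.float32), spec.voxel_size, meta={"units": "1/mm"})


def _analytic_truth(spec: PhantomSpec) -> dict:
    """Ground-truth measurement table, computed from the spec (not the raster)."""
    s = spec.cross_section_scale
    vs_mm = spec.voxel_size / UM_PER_MM
    L = spec.centerline_arclength_mm()
    L_rwm = spec.centerline_arclength_mm(spec.rwm_angular_thickness())
    r_st = spec.scala_tympani_radius * s / UM_PER_MM
    r_sv = spec.scala_vestibuli_radius * s / UM_PER_MM
    u_in, u_out = spec.envelope_u
    margin = (u_out * s + spec.capsule_thickness) / UM_PER_MM
    r0 = spec.spiral_radius(0.0) / UM_PER_MM
    r180 = spec.spiral_radius(180.0) / UM_PER_MM
    r90 = spec.spiral_radius(90.0) / UM_PER_MM
    r270 = spec.spiral_radius(270.0) / UM_PER_MM
    height = (
        spec.pitch * spec.turns + 2 * (spec.envelope_w * s + spec.capsule_thickness)
    ) / UM_PER_MM
    return {
        "turns": spec.turns,
        "angular_extent_deg": spec.angular_extent,
        "ssl_range_deg": (0.0, spec.ssl_end),
        "rwa_range_deg": (0.0, spec.rwa_end),
        "rc_range_deg": (spec.rc_start, spec.rc_end),
        "centerline_length_mm": L,
        "st_volume_mm3": np.pi * r_st**2 * (L - L_rwm),
        "sv_volume_mm3": np.pi * r_sv**2 * L,
        "bm_thickness_mm": spec.bm_thickness / UM_PER_MM,
        "rm_thickness_mm": spec.rm_thickness / UM_PER_MM,
        "rwm_thickness_mm": spec.rwm_thickness / UM_PER_MM,
        "length_mm": r0 + r180 + 2 * margin,
        "width_mm": r90 + r270 + 2 * margin,
        "height_mm": height,
        "voxel_size_mm": vs_mm,
    }


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the spiral cochlea described by ``spec``.

    Raises a ``ValueError`` naming the structure if any structure would be
    thinner than one voxel at the requested voxel size.
    """
    from .coords import CochlearFrame  # local import to avoid a module cycle

    spec.validate()
    theta, u, w, (z0, cy, cx) = _tube_coordinates(spec)
    lab = _classify(spec, theta, u, w)
    if spec.parafilm_block:
        _place_parafilm(spec, lab)
    # ground-truth tube coordinates only where anatomy exists
    anatomy = (lab != 0) & (lab != LABELS["parafilm"])
    theta = np.where(anatomy, theta, np.nan)
    u = np.where(anatomy, u, np.nan)
    w = np.where(anatomy, w, np.nan)

    grey = _grey_from_labels(spec, lab)
    labels = LabelVolume(lab, spec.voxel_size, dict(LABELS))
    frame = CochlearFrame(
        axis_point_mm=np.array([cx, cy, z0]) / UM_PER_MM,
        axis_dir=np.array([0.0, 0.0, 1.0]),
        zero_dir=np.array([1.0, 0.0, 0.0]),
        handedness=spec.handedness,
    )
    return Phantom(
        spec=spec,
        grey=grey,
        labels=labels,
        frame=frame,
        truth=_analytic_truth(spec),
        theta=theta,
        u=u,
        w=w,
    )


# ---------------------------------------------------------------------------
# staining time-course


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def stain_uptake(
    phantom: Phantom,
    time_h: float,
    rate_turns_per_day: float = 1.0,
    front_width_deg: float = 30.0,
) -> StainState:
    """Per-voxel contrast uptake of the base-to-apex staining front.

    The front advances ``rate`` turns/day along the unwrapped angle; uptake
    falls off as a logistic of angular distance to the front.  The RWM is in
    direct contact with the staining bath and is fully stained from 3 h on.
    A voxel counts as *stained* once its uptake reaches 0.5, i.e. once the
    front has passed it.
    """
    if time_h < 0:
        raise ValueError("time must be >= 0")
    if rate_turns_per_day <= 0:
        raise ValueError("rate must be > 0")
    front = rate_turns_per_day * (time_h / 24.0) * 360.0
    if time_h == 0:
        uptake = np.zeros(phantom.labels.shape, dtype=np.float32)
    else:
        uptake = _logistic((front - phantom.theta) / front_width_deg).astype(np.float32)
        uptake[~np.isfinite(phantom.theta)] = 0.0
    if time_h >= 3.0:
        uptake[phantom.labels.data == LABELS["rwm"]] = 1.0
    return StainState(time_h, rate_turns_per_day, front_width_deg, uptake)


def simulate_staining(
    phantom: Phantom,
    time_h: float,
    rate_turns_per_day: float = 1.0,
    front_width_deg: float = 30.0,
) -> tuple[Volume3D, StainState]:
    """Grey volume of the phantom after ``time_h`` hours of submersion."""
    state = stain_uptake(phantom, time_h, rate_turns_per_day, front_width_deg)
    grey = _grey_from_labels(phantom.spec, phantom.labels.data, uptake=state.uptake)
    return grey, state


# ---------------------------------------------------------------------------
# electrode insertion and trauma ground truth

#: (structure, lesion kind) -> Eshraghi descriptor
_DESCRIPTOR_MAP = {
    ("bm", "elevation"): "BM elevation",
    ("bm", "deformation"): "BM elevation",
    ("bm", "tear"): "BM rupture",
    ("bm", "fracture"): "BM rupture",
    ("cpb_ooc", "tear"): "BM rupture",
    ("cpb_ooc", "fracture"): "BM rupture",
    ("osl", "fracture"): "OSL fracture",
    ("osl", "tear"): "OSL fracture",
    ("sl", "tear"): "SL/stria tear",
    ("sl", "fracture"): "SL/stria tear",
}


def insert_electrode(
    phantom: Phantom,
    depth_deg: float,
    lesions: tuple[Lesion, ...] | list[Lesion] = (),
    electrode_radius_um: float = 90.0,
) -> Phantom:
    """Trace an electrode along the scala tympani to ``depth_deg`` and apply lesions.

    The electrode only overwrites open fluid (it enters just past the RWM,
    so an untraumatized insertion leaves every anatomy label untouched).
    Lesion kinds: ``fracture``/``tear`` remove structure voxels in the
    angular range (they become ST fluid); ``elevation``/``deformation``
    displace them axially by two voxels; ``scala-vestibuli translocation``
    routes the electrode into the scala vestibuli through a BM rupture.
    Returns a new post-insertion Phantom with a ground-truth lesion table.
    """
    spec = phantom.spec
    extent = spec.angular_extent
    if not 0 < depth_deg <= extent:
        raise ValueError(f"depth must be in (0, {extent}]")
    for les in lesions:
        if les.structure not in LABELS:
            raise ValueError(f"unknown structure {les.structure!r}")
        if les.kind not in Lesion.KINDS:
            raise ValueError(f"unknown lesion kind {les.kind!r}")
        if les.theta_end > depth_deg:
            raise ValueError(
                f"lesion range ({les.theta_start}-{les.theta_end}°) beyond "
                f"electrode depth {depth_deg}°"
            )
        if les.theta_start >= les.theta_end:
            raise ValueError("lesion angular range is empty")

    lab = phantom.labels.data.copy()
    pre = phantom.labels.data
    th, uu, ww = phantom.theta, phantom.u, phantom.w
    s = spec.cross_section_scale
    st_fluid = LABELS["scala_tympani"]
    vox_mm3 = (spec.voxel_size / UM_PER_MM) ** 3

    rows = []

    def _record(structure: str, kind: str, les: Lesion, affected: int, descriptor: str | None):
        pre_n = int((pre == LABELS[structure]).sum())
        rows.append(
            {
                "structure": structure,
                "kind": kind,
                "theta_start": les.theta_start,
                "theta_end": les.theta_end,
                "affected_voxels": affected,
                "affected_mm3": affected * vox_mm3,
                "pre_voxels": pre_n,
                "affected_pct": 100.0 * affected / pre_n if pre_n else np.nan,
                "descriptor": descriptor,
            }
        )

    translocations = [l for l in lesions if l.kind == "scala-vestibuli translocation"]
    for les in lesions:
        if les.kind in ("fracture", "tear"):
            sel = (
                (lab == LABELS[les.structure])
                & (th >= les.theta_start)
                & (th <= les.theta_end)
            )
            n = int(sel.sum())
            lab[sel] = st_fluid
            _record(
                les.structure,
                les.kind,
                les,
                n,
                _DESCRIPTOR_MAP.get((les.structure, les.kind)),
            )
        elif les.kind in ("elevation", "deformation"):
            sel = (
                (lab == LABELS[les.structure])
                & (th >= les.theta_start)
                & (th <= les.theta_end)
            )
            shifted = np.zeros_like(sel)
            shifted[2:, :, :] = sel[:-2, :, :]
            # displaced tissue can move into fluid or the loose filler of the
            # capsule envelope, but not into other structures
            soft_ids = [LABELS[n] for n in FLUID_STRUCTURES] + [LABELS["capsule"]]
            landing = shifted & np.isin(lab, soft_ids)
            lab[sel] = st_fluid
            lab[landing] = LABELS[les.structure]
            affected = int(sel.sum()) + int(landing.sum()) - 2 * int((sel & landing).sum())
            _record(
                les.structure,
                les.kind,
                les,
                affected,
                _DESCRIPTOR_MAP.get((les.structure, les.kind)),
            )

    # electrode path: ST center, entering just past the RWM cap, except
    # through translocated ranges (SV center)
    rwm_span = spec.rwm_angular_thickness()
    in_depth = (th > rwm_span / 2.0) & (th <= depth_deg)
    d_path = np.hypot(uu - 0.0, ww + spec.st_offset * s)
    elec = in_depth & (d_path <= electrode_radius_um)
    for les in translocations:
        rng_sel = (th >= les.theta_start) & (th <= les.theta_end)
        d_sv = np.hypot(uu - 0.0, ww - spec.sv_offset * s)
        elec = np.where(rng_sel, rng_sel & in_depth & (d_sv <= electrode_radius_um), elec)
        # the electrode crosses the cochlear partition: rupture the BM there
        bm_cross = (
            (lab == LABELS["bm"])
            & (th >= les.theta_start)
            & (th <= les.theta_end)
            & (np.abs(uu) <= 3 * electrode_radius_um)
        )
        n = int(bm_cross.sum())
        lab[bm_cross] = st_fluid
        _record("bm", "tear", les, n, "BM rupture")
        _record(les.structure, les.kind, les, 0, "electrode in scala vestibuli")

    fluid_ids = [LABELS[n] for n in FLUID_STRUCTURES]
    lab[elec & np.isin(lab, fluid_ids)] = LABELS["electrode"]

    grey = _grey_from_labels(spec, lab)
    table = pd.DataFrame(
        rows,
        columns=[
            "structure",
            "kind",
            "theta_start",
            "theta_end",
            "affected_voxels",
            "affected_mm3",
            "pre_voxels",
            "affected_pct",
            "descriptor",
        ],
    )
    truth = dict(phantom.truth)
    truth["electrode_depth_deg"] = depth_deg
    return Phantom(
        spec=spec,
        grey=grey,
        labels=LabelVolume(lab, spec.voxel_size, dict(LABELS)),
        frame=phantom.frame,
        truth=truth,
        theta=th,
        u=uu,
        w=ww,
        lesion_table=table,
    )


# ---------------------------------------------------------------------------
# high-resolution membrane patch (thickness-recovery fixture)


def membrane_patch(
    thickness_um: float = 170.0,
    voxel_size_um: float = 6.3,
    curvature_radius_um: float = 1200.0,
    grid_shape: tuple[int, int, int] = (56, 96, 96),
) -> LabelVolume:
    """A curved membrane of uniform thickness, rasterized at high resolution.

    The patch is a spherical-shell segment spanning the full lateral extent
    of the grid (so the thickness map has no lateral cut artifacts),
    emulating a cropped high-resolution scan of the round window membrane.
    """
    if thickness_um < voxel_size_um:
        raise ValueError("membrane thinner than one voxel")
    nz, ny, nx = grid_shape
    vs = voxel_size_um
    z = (np.arange(nz) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    x = (np.arange(nx) + 0.5) * vs
    cx, cy = x.mean(), y.mean()
    cz = z.mean() - curvature_radius_um
    Z, Y, X = np.meshgrid(z - cz, y - cy, x - cx, indexing="ij")
    d = np.sqrt(X**2 + Y**2 + Z**2)
    mask = (d >= curvature_radius_um - thickness_um / 2.0) & (
        d < curvature_radius_um + thickness_um / 2.0
    )
    lab = np.where(mask, LABELS["rwm"], 0).astype(np.uint8)
    return LabelVolume(lab, voxel_size_um, {"rwm": LABELS["rwm"]})


# ---------------------------------------------------------------------------
# dimension-targeted parameterization


def spec_from_dimensions(
    length_um: float,
    width_um: float,
    height_um: float,
    turns: float,
    base: PhantomSpec | None = None,
    **overrides,
) -> PhantomSpec:
    """Solve spiral parameters so the phantom's outer extents hit given targets.

    Inverts the closed-form extent expressions: the cross-section scale comes
    from the height budget (keeping inter-turn clearance), the basal radius
    from the width, and the in-plane ellipticity from the length surplus over
    a circular spiral.
    """
    base = base or PhantomSpec()
    d = base.radius_decay
    c = base.capsule_thickness
    ew = base.envelope_w
    u_out = base.envelope_u[1]
    # height = pitch*turns + 2*(ew*s + c) with pitch = 1.15*(2*(sv_offset+r_sv)*s + 100)
    half_cs = base.sv_offset + base.scala_vestibuli_radius
    s = (height_um - 2 * c - 115.0 * turns) / (2 * ew + 1.15 * 2 * half_cs * turns)
    s = float(np.clip(s, 0.3, 1.0))
    pitch = (height_um - 2 * (ew * s + c)) / turns
    margin = 2 * (u_out * s + c)
    r0 = (width_um - margin) / (2.0 - d)
    ell = (length_um - margin) / (r0 * (2.0 - d / 2.0)) - 1.0
    ell = max(ell, 0.0)
    kwargs = dict(
        turns=turns,
        basal_radius=r0,
        ellipticity=ell,
        pitch=pitch,
        cross_section_scale=s,
    )
    kwargs.update(overrides)
    return replace(base, **kwargs)


def calibrate_spec_to_dimensions(
    length_um: float,
    width_um: float,
    height_um: float,
    turns: float,
    base: PhantomSpec | None = None,
    rounds: int = 2,
    **overrides,
) -> PhantomSpec:
    """Refine ``spec_from_dimensions`` against the rasterized measurement.

    Generation and measurement quantize extents to the voxel grid; one or two
    fixed-point rounds remove that residual.  Measurement uses the package's
    own frame fit and dimension convention.
    """
    from . import coords

    target = np.array([length_um, width_um, height_um], dtype=float)
    goal = target.copy()
    spec = spec_from_dimensions(*target, turns, base=base, **overrides)
    best_spec, best_err = spec, np.inf
    for _ in range(rounds + 1):
        ph = generate_phantom(spec)
        frame = coords.fit_frame(ph.labels)
        dims = coords.measure_cochlea_dimensions(ph.labels, frame)
        measured = np.array([dims["length"], dims["width"], dims["height"]]) * UM_PER_MM
        err = measured - goal
        worst = float(np.abs(err).max())
        if worst < best_err:
            best_spec, best_err = spec, worst
        # extents quantize to the voxel grid: half a voxel is convergence
        if worst <= spec.voxel_size / 2:
            break
        target = target - err
        spec = spec_from_dimensions(*target, turns, base=base, **overrides)
    return best_spec
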