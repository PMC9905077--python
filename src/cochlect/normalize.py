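"""Grey-value conditioning: bit-depth windowing, two-reference normalization,
downsampling, reference contrast, and soft-tissue visibility grading.

Scans from different days live on different grey scales; matching the mean
grey of two reference materials — the cortical bone of the cochlear capsule
and a parafilm foil analog — with a two-point affine map puts them on a
common scale.  Soft-tissue visibility per turn is graded 0–3: 0 not
visible, 1 partially visible on some slices, 2 partially visible on all
slices, 3 entirely visible on all slices.  The automated grading is a proxy
for a human grader: "visible" means the voxel exceeds the local fluid grey
by a contrast threshold, and "slices" are transmodiolar angular sectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelVolume, Volume3D
from .coords import CochlearFrame, SpiralReference, angular_position, build_reference

__all__ = [
    "ReferencePair",
    "VisibilityGrade",
    "window_to_8bit",
    "normalize_to_references",
    "downsample",
    "reference_contrast",
    "grade_visibility",
    "references_from_labels",
]

#: soft-tissue structures graded for visibility (Fig-1-style follow-up)
GRADED_STRUCTURES = ("bm", "sl", "rm", "cpb_ooc")


@dataclass
class ReferencePair:
    """Masks and target grey values of the two normalization references."""

    mask_a: np.ndarray  # cortical bone (cochlear capsule)
    mask_b: np.ndarray  # parafilm foil analog
    target_a: float = 200.0
    target_b: float = 40.0

    def __post_init__(self) -> None:
        if not self.mask_a.any() or not self.mask_b.any():
            raise ValueError("reference masks must be non-empty")
        if (self.mask_a & self.mask_b).any():
            raise ValueError("reference masks must be disjoint")
        if self.target_a == self.target_b:
            raise ValueError("reference targets must differ")

    def means(self, volume: Volume3D) -> tuple[float, float]:
        return float(volume.data[self.mask_a].mean()), float(volume.data[self.mask_b].mean())


def references_from_labels(
    labels: LabelVolume, target_a: float = 200.0, target_b: float = 40.0
) -> ReferencePair:
    """Build the reference pair from 'capsule' and 'parafilm' labels."""
    return ReferencePair(labels.mask("capsule"), labels.mask("parafilm"), target_a, target_b)


@dataclass
class VisibilityGrade:
    """Per structure and cochlear turn: the 0–3 grade and its evidence."""

    structure: str
    turn: int
    grade: int
    slice_fractions: np.ndarray  # visible fraction per transmodiolar sector

    def consistent(self, entire_threshold: float = 0.95) -> bool:
        """Re-derive the grade from the per-slice fractions."""
        return self.grade == _grade_from_fractions(self.slice_fractions, entire_threshold)


def _grade_from_fractions(
    fracs: np.ndarray, entire_threshold: float = 0.95, partial_threshold: float = 0.05
) -> int:
    """0–3 grade from per-slice visible fractions.

    A slice is 'entire' at ≥ ``entire_threshold`` visible voxels and
    'partial' at ≥ ``partial_threshold`` (the floor keeps isolated noise
    voxels from counting as visibility).
    """
    if fracs.size == 0:
        return 0
    if np.all(fracs >= entire_threshold):
        return 3
    partial = fracs >= partial_threshold
    if np.all(partial):
        return 2
    if np.any(partial):
        return 1
    return 0


# ---------------------------------------------------------------------------
# grey-value maps


def window_to_8bit(volume: Volume3D, lo_pct: float = 0.1, hi_pct: float = 99.9) -> Volume3D:
    """Window the histogram to [lo, hi] percentiles and rescale to 8 bits.

    Values at or below the low percentile map to 0, at or above the high
    percentile to 255, linearly in between (a monotone map).
    """
    if not 0 <= lo_pct < hi_pct <= 100:
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    lo, hi = np.percentile(volume.data, [lo_pct, hi_pct])
    if hi == lo:
        raise ValueError("zero dynamic range: constant volume cannot be windowed")
    scaled = (volume.data.astype(np.float64) - lo) / (hi - lo)
    out = np.clip(np.round(scaled * 255.0), 0, 255).astype(np.uint8)
    meta = dict(volume.meta, window=(float(lo), float(hi)), bits=8)
    return Volume3D(out, volume.voxel_size_um, meta)


def normalize_to_references(volume: Volume3D, refs: ReferencePair) -> Volume3D:
    """Affine map sending mean(A) → target(A) and mean(B) → target(B).

    The unique monotone linear map matching both references; applying it
    twice equals applying it once (up to rounding for integer volumes).
    """
    mean_a, mean_b = refs.means(volume)
    if mean_a == mean_b:
        raise ValueError("degenerate references: equal mean grey values")
    gain = (refs.target_a - refs.target_b) / (mean_a - mean_b)
    offset = refs.target_a - gain * mean_a
    data = volume.data.astype(np.float64) * gain + offset
    if np.issubdtype(volume.data.dtype, np.integer):
        info = np.iinfo(volume.data.dtype)
        data = np.clip(np.round(data), info.min, info.max).astype(volume.data.dtype)
    else:
        data = data.astype(volume.data.dtype)
    meta = dict(volume.meta, normalization={"gain": gain, "offset": offset})
    return Volume3D(data, volume.voxel_size_um, meta)


def downsample(volume: Volume3D, factor: int) -> Volume3D:
    """Block-mean binning by an integer factor; voxel size scales with it.

    Dimensions that are not multiples of the factor are cropped to the
    largest multiple (with a warning).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return volume.copy()
    shape = volume.shape
    new = tuple(s // factor for s in shape)
    if any(n == 0 for n in new):
        raise ValueError("factor larger than the volume")
    crop = tuple(n * factor for n in new)
    if crop != shape:
        import warnings

        warnings.warn(f"cropping {shape} to {crop} (not a multiple of {factor})")
    d = volume.data[: crop[0], : crop[1], : crop[2]].astype(np.float64)
    d = d.reshape(new[0], factor, new[1], factor, new[2], factor).mean(axis=(1, 3, 5))
    if np.issubdtype(volume.data.dtype, np.integer):
        d = np.round(d).astype(volume.data.dtype)
    else:
        d = d.astype(volume.data.dtype)
    return Volume3D(d, volume.voxel_size_um * factor, dict(volume.meta))


def reference_contrast(volume: Volume3D, refs: ReferencePair) -> float:
    """Contrast-to-noise ratio between the two reference materials.

    |mean(A) − mean(B)| divided by the pooled standard deviation.
    """
    a = volume.data[refs.mask_a].astype(np.float64)
    b = volume.data[refs.mask_b].astype(np.float64)
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled <= 1e-12 * max(abs(a.mean()), abs(b.mean()), 1.0):
        raise ValueError("zero pooled standard deviation: CNR undefined")
    return float(abs(a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# visibility grading


def grade_visibility(
    volume: Volume3D,
    labels: LabelVolume,
    frame: CochlearFrame,
    contrast_threshold: float,
    reference: SpiralReference | None = None,
    structures: tuple[str, ...] = GRADED_STRUCTURES,
    sector_deg: float = 10.0,
    entire_threshold: float = 0.95,
) -> list[VisibilityGrade]:
    """Grade soft-tissue visibility per structure and cochlear turn (0–3).

    A structure voxel is visible when its grey exceeds the mean fluid grey
    of its angular sector by at least ``contrast_threshold``.  Transmodiolar
    slices are emulated by angular sectors of ``sector_deg``; a sector is
    'entire' when ≥ ``entire_threshold`` of its structure voxels are visible.
    """
    for s in structures:
        if s not in labels.names or not (labels.data == labels.names[s]).any():
            raise ValueError(f"structure {s!r} absent from labels")
    reference = reference or build_reference(labels, frame)
    vs = labels.voxel_size_um

    fluid_names = [n for n in ("scala_tympani", "scala_vestibuli", "scala_media", "fluid") if n in labels.names]
    fluid_mask = np.isin(labels.data, [labels.names[n] for n in fluid_names])
    f_idx = np.argwhere(fluid_mask)
    f_idx = f_idx[:: max(1, len(f_idx) // 100_000)]
    f_pts = (f_idx[:, ::-1] + 0.5) * vs / 1000.0
    f_theta = angular_position(f_pts, frame, reference)
    f_grey = volume.data[f_idx[:, 0], f_idx[:, 1], f_idx[:, 2]].astype(np.float64)

    n_sectors = int(np.ceil((reference.theta_max + 90.0) / sector_deg))
    fluid_sector = np.clip((f_theta / sector_deg).astype(int), 0, n_sectors - 1)
    fluid_mean = np.full(n_sectors, np.nan)
    df = pd.DataFrame({"s": fluid_sector, "g": f_grey}).groupby("s")["g"].mean()
    fluid_mean[df.index.values] = df.values
    # fill sectors without fluid from the global fluid mean
    fluid_mean = np.where(np.isnan(fluid_mean), np.nanmean(fluid_mean), fluid_mean)

    grades: list[VisibilityGrade] = []
    for s in structures:
        idx = np.argwhere(labels.data == labels.names[s])
        pts = (idx[:, ::-1] + 0.5) * vs / 1000.0
        theta = angular_position(pts, frame, reference)
        grey = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
        sector = np.clip((theta / sector_deg).astype(int), 0, n_sectors - 1)
        visible = grey >= fluid_mean[sector] + contrast_threshold
        turn = np.clip(theta // 360.0, 0, None).astype(int) + 1
        for t in np.unique(turn):
            sel = turn == t
            tab = pd.DataFrame({"sec": sector[sel], "vis": visible[sel]}).groupby("sec")["vis"].mean()
            fracs = tab.values
            grades.append(VisibilityGrade(s, int(t), _grade_from_fractions(fracs, entire_threshold), fracs))
    return grades


def grades_to_frame(grades: list[VisibilityGrade], **extra) -> pd.DataFrame:
    """Tabulate grades (one row per structure × turn), Fig-1C-style layout."""
    rows = [
        dict(structure=g.structure, turn=g.turn, grade=g.grade, **extra) for g in grades
    ]
    return pd.DataFrame(rows, columns=["structure", "turn", "grade", *extra.keys()])
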