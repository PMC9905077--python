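"""Electrode insertion trauma quantification from pre/post label volumes.

Pre- and post-insertion segmentations on the same grid are differenced per
structure; electrode-occupied voxels inside an open scala do not count as
trauma (intrascalar position is not damage), while voxels lost from any
anatomy label do.  Each structure's trauma is summarized by its volume,
the percentage of the pre-insertion structure volume, its angular range,
bounding dimensions and centerline length, and an Eshraghi grade:

    0  no observable trauma
    1  elevation of the basilar membrane
    2  rupture of the basilar membrane
    3  electrode in the scala vestibuli
    4  severe trauma: fracture of the OSL or modiolus, or tear of the
       stria vascularis within the spiral ligament

Structures thinner than two segmentation voxels get a volume-unreliable
flag (their rasterized volume is not meaningful at that resolution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LabelVolume, UM_PER_MM
from .coords import CochlearFrame, SpiralReference, angular_position, build_reference, _points_mm
from . import morphometry

__all__ = [
    "ESHRAGHI_SCALE",
    "diff_structures",
    "traumatized_fraction",
    "insertion_depth",
    "eshraghi_grade",
    "build_trauma_report",
]

#: Eshraghi grading scale: descriptor -> ordinal grade
ESHRAGHI_SCALE: dict[str, int] = {
    "none": 0,
    "BM elevation": 1,
    "BM rupture": 2,
    "electrode in scala vestibuli": 3,
    "OSL fracture": 4,
    "modiolus fracture": 4,
    "SL/stria tear": 4,
}

_FLUID_NAMES = ("scala_tympani", "scala_vestibuli", "scala_media", "fluid")


def eshraghi_grade(descriptors) -> int:
    """Grade of a set of trauma descriptors: the maximum grade present.

    Descriptors come from the controlled vocabulary of
    :data:`ESHRAGHI_SCALE`; an empty set grades 0 (no observable trauma).
    """
    grade = 0
    for d in descriptors:
        if d not in ESHRAGHI_SCALE:
            raise ValueError(f"unknown trauma descriptor {d!r}; known: {sorted(ESHRAGHI_SCALE)}")
        grade = max(grade, ESHRAGHI_SCALE[d])
    return grade


def diff_structures(pre: LabelVolume, post: LabelVolume) -> dict[str, np.ndarray]:
    """Per-structure trauma masks: voxels that left the structure's label.

    Voxels that merely changed from an open fluid compartment to the
    electrode label are excluded — the electrode occupying a scala is not
    trauma.  Displaced structures appear through the symmetric label
    difference (lost and gained voxels both count once).
    """
    if pre.shape != post.shape or pre.voxel_size_um != post.voxel_size_um:
        raise ValueError("pre/post grids differ")
    masks: dict[str, np.ndarray] = {}
    for name, lid in pre.names.items():
        if name in ("electrode", "parafilm", "capsule"):
            continue
        pre_m = pre.data == lid
        if not pre_m.any():
            continue
        post_m = post.data == lid
        lost = pre_m & ~post_m
        gained = post_m & ~pre_m
        if name in _FLUID_NAMES:
            # a fluid compartment is not traumatized by being occupied — by
            # the electrode or by a displaced neighbouring structure
            lost &= post.data == 0
            gained &= False
        masks[name] = lost | gained
    return masks


def traumatized_fraction(pre: LabelVolume, trauma_mask: np.ndarray, structure: str) -> float:
    """Percent of the pre-insertion structure volume affected by trauma."""
    n_pre = int(pre.mask(structure).sum())  # raises if empty: loud absence
    return 100.0 * float(trauma_mask.sum()) / n_pre


def insertion_depth(
    electrode_mask: np.ndarray,
    frame: CochlearFrame,
    voxel_size_um: float,
    reference: SpiralReference,
) -> float:
    """Angular insertion depth: maximal unwrapped angle over electrode voxels."""
    if not electrode_mask.any():
        raise ValueError("empty electrode mask")
    pts = _points_mm(electrode_mask, voxel_size_um)
    theta = angular_position(pts, frame, reference)
    return float(theta.max())


#: descriptor inferred from a structure's trauma evidence: (structure, mode)
_AUTO_DESCRIPTOR = {
    ("bm", "removed"): "BM rupture",
    ("bm", "displaced"): "BM elevation",
    ("cpb_ooc", "removed"): "BM rupture",
    ("osl", "removed"): "OSL fracture",
    ("sl", "removed"): "SL/stria tear",
    ("rc", "removed"): "modiolus fracture",
}


def build_trauma_report(
    pre: LabelVolume,
    post: LabelVolume,
    frame: CochlearFrame,
    reference: SpiralReference | None = None,
    thickness_lookup_um: dict[str, float] | None = None,
    min_trauma_voxels: int = 1,
) -> pd.DataFrame:
    """Full per-structure trauma report from a pre/post pair.

    Columns mirror the trauma-overview table: structure, angular position
    (start/end, deg), max dimensions (mm), centerline length (mm), trauma
    volume (mm³), percent of pre-insertion volume, descriptor, Eshraghi
    grade, and a volume-unreliable flag for structures whose ground-truth
    thickness is below two segmentation voxels.  The final row carries the
    overall insertion depth and composite (maximum) grade.
    """
    reference = reference or build_reference(post, frame)
    masks = diff_structures(pre, post)
    vs = pre.voxel_size_um
    vox_mm3 = (vs / UM_PER_MM) ** 3

    elec_descr: set[str] = set()
    if "electrode" in post.names and (post.data == post.names["electrode"]).any():
        elec_mask = post.data == post.names["electrode"]
        depth = insertion_depth(elec_mask, frame, vs, reference)
        # electrode voxels in the scala vestibuli indicate a translocation
        sv = pre.names.get("scala_vestibuli")
        if sv is not None and (elec_mask & (pre.data == sv)).sum() >= min_trauma_voxels:
            elec_descr.add("electrode in scala vestibuli")
    else:
        depth = np.nan

    rows = []
    grades = [0]
    for name, mask in masks.items():
        n = int(mask.sum())
        if n < min_trauma_voxels:
            continue
        pts = _points_mm(mask, vs)
        theta = angular_position(pts, frame, reference)
        dims = pts.max(axis=0) - pts.min(axis=0) + vs / UM_PER_MM
        length, _ = morphometry.centerline_length(mask, vs)
        pct = traumatized_fraction(pre, mask, name)
        lost_n = int(((pre.data == pre.names[name]) & mask).sum())
        gained_n = int(((post.data == pre.names[name]) & mask).sum())
        # a displaced structure reappears next to where it vanished
        mode = "displaced" if gained_n >= 0.3 * max(lost_n, 1) else "removed"
        descriptor = _AUTO_DESCRIPTOR.get((name, mode))
        grade = ESHRAGHI_SCALE.get(descriptor, 0) if descriptor else 0
        grades.append(grade)
        unreliable = False
        if thickness_lookup_um and name in thickness_lookup_um:
            unreliable = thickness_lookup_um[name] < 2 * vs
        rows.append(
            {
                "structure": name,
                "theta_start_deg": float(max(theta.min(), 0.0)),
                "theta_end_deg": float(theta.max()),
                "max_dim_mm": float(dims.max()),
                "centerline_length_mm": length,
                "trauma_volume_mm3": n * vox_mm3,
                "percent_of_pre": pct,
                "descriptor": descriptor,
                "eshraghi_grade": grade,
                "volume_unreliable": unreliable,
            }
        )

    for d in elec_descr:
        grades.append(ESHRAGHI_SCALE[d])
    overall = max(grades)
    rows.append(
        {
            "structure": "overall",
            "theta_start_deg": 0.0,
            "theta_end_deg": depth,
            "max_dim_mm": np.nan,
            "centerline_length_mm": np.nan,
            "trauma_volume_mm3": float(sum(r["trauma_volume_mm3"] for r in rows)),
            "percent_of_pre": np.nan,
            "descriptor": "; ".join(sorted(elec_descr)) or None,
            "eshraghi_grade": overall,
            "volume_unreliable": False,
        }
    )
    df = pd.DataFrame(rows)
    df.attrs["insertion_depth_deg"] = depth
    df.attrs["composite_grade"] = overall
    df.attrs["convention"] = (
        "trauma = symmetric label difference excluding electrode-occupied fluid; "
        "percent is voxel-weighted relative to the pre-insertion structure"
    )
    return df
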