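"""Shared fixtures: desk-scale phantom, small fast phantom, geometry helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from cochlect import coords
from cochlect.phantom import Lesion, PhantomSpec, generate_phantom, insert_electrode

#: spec overrides for a coarse, fast phantom (96³ at 70 µm; membranes and
#: canals thickened to stay above one voxel)
FAST_KW = dict(
    grid_shape=(96, 96, 96),
    voxel_size=70.0,
    bm_thickness=80.0,
    rm_thickness=75.0,
    rwm_thickness=150.0,
    osl_thickness=140.0,
    scala_media_radius=75.0,
    rc_radius=140.0,
    rwa_thickness=120.0,
    ssl_width=160.0,
    ssl_height=130.0,
)


def fast_spec(**overrides) -> PhantomSpec:
    kw = dict(FAST_KW)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def desk_phantom():
    """Default desk-scale phantom: 2.8 turns, SSL to 572°, 192³ at 35 µm."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def desk_frame(desk_phantom):
    return coords.fit_frame(desk_phantom.labels)


@pytest.fixture(scope="session")
def desk_reference(desk_phantom, desk_frame):
    return coords.build_reference(desk_phantom.labels, desk_frame)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(fast_spec())


@pytest.fixture(scope="session")
def post_phantom(desk_phantom):
    """Desk phantom after a 380° insertion with three canonical lesions."""
    lesions = [
        Lesion("osl", "fracture", 120.0, 180.0),
        Lesion("sl", "tear", 200.0, 260.0),
        Lesion("bm", "elevation", 90.0, 130.0),
    ]
    return insert_electrode(desk_phantom, 380.0, lesions)


def helix_mask(
    radius_um: float = 1200.0,
    pitch_um: float = 1000.0,
    turns: float = 2.0,
    tube_radius_um: float = 250.0,
    voxel_size_um: float = 40.0,
):
    """Rasterized helical tube plus its analytic arc length (mm)."""
    vs = voxel_size_um
    ng = int(2 * (radius_um + tube_radius_um) / vs) + 12
    nz = int((pitch_um * turns + 2 * tube_radius_um) / vs) + 12
    th = np.linspace(0, turns * 2 * np.pi, 4000)
    centerline = np.stack(
        [radius_um * np.cos(th), radius_um * np.sin(th), pitch_um * th / (2 * np.pi)], axis=1
    )
    zz, yy, xx = np.mgrid[:nz, :ng, :ng].astype(float)
    pts = np.stack([(xx - ng / 2) * vs, (yy - ng / 2) * vs, (zz - 4) * vs], axis=-1)
    d, _ = cKDTree(centerline).query(pts.reshape(-1, 3))
    mask = d.reshape(nz, ng, ng) <= tube_radius_um
    arc_mm = turns * np.sqrt((2 * np.pi * radius_um / 1000.0) ** 2 + (pitch_um / 1000.0) ** 2)
    return mask, arc_mm


def random_blob(seed: int, n: int = 40):
    """Smooth random 3D blob mask for thickness tests."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.normal(size=(n, n, n)), sigma=4.0)
    return noise > np.quantile(noise, 0.7)


def brute_force_thickness(mask: np.ndarray, step_voxels: int = 2) -> np.ndarray:
    """Exhaustive maximal-inscribed-sphere thickness (voxels), the slow oracle.

    For every mask voxel as a candidate sphere center with quantized radius
    R = ceil(EDT/(step/2))·step/2, paint diameter 2R−1 over all voxels within
    Euclidean distance R−1; thickness is the max diameter covering each voxel.
    """
    from scipy.ndimage import distance_transform_edt

    edt = distance_transform_edt(mask)
    h = step_voxels / 2.0
    out = np.zeros(mask.shape)
    centers = np.argwhere(mask)
    shape = np.array(mask.shape)
    for c in centers:
        r = np.ceil((edt[tuple(c)] - 1e-9) / h) * h
        d = 2.0 * r - 1.0
        reach = int(np.floor(r - 1.0 + 1e-9))
        lo = np.maximum(c - reach, 0)
        hi = np.minimum(c + reach + 1, shape)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= (r - 1.0 + 1e-9) ** 2
        win = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        win[inside] = np.maximum(win[inside], d)
    return np.where(mask, out, 0.0)
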