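"""Volume I/O: TIFF slice stacks with JSON sidecars.

Grey volumes travel as 16-bit TIFF slices (numbered single-page files or
one multi-page file), label volumes as 8-bit TIFF plus a JSON label-name
map, sinograms as 32-bit float TIFF.  Voxel size and metadata live in a
``<name>.json`` sidecar next to the stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import LabelVolume, Volume3D

__all__ = ["save_stack", "load_stack", "save_labels", "load_labels"]

_ALLOWED_DTYPES = {np.dtype(k) for k in ("uint8", "uint16", "float32")}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json") if path.suffix else path / "stack.json"


def save_stack(volume: Volume3D, path: str | Path, multipage: bool = True) -> Path:
    """Write a volume as TIFF (multi-page file or numbered slices) + sidecar."""
    path = Path(path)
    if volume.data.dtype not in _ALLOWED_DTYPES:
        raise ValueError(f"unsupported dtype {volume.data.dtype}; use uint8/uint16/float32")
    if multipage:
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, volume.data)
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(volume.shape[0])))
        for i, sl in enumerate(volume.data):
            tifffile.imwrite(path / f"slice_{i:0{width}d}.tif", sl)
    side = _sidecar(path)
    side.write_text(
        json.dumps(
            {"voxel_size_um": volume.voxel_size_um, "dtype": str(volume.data.dtype), "meta": _jsonable(volume.meta)},
            indent=1,
        )
    )
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_stack(path: str | Path) -> Volume3D:
    """Read a TIFF stack written by :func:`save_stack` (either dialect).

    Numbered slices must agree in shape and dtype; inconsistent slices or
    unsupported bit depths are errors.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("slice_*.tif"))
        if not files:
            raise FileNotFoundError(f"no slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        dtypes = {s.dtype for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
        if len(dtypes) > 1:
            raise ValueError(f"mixed slice dtypes in one stack: {sorted(map(str, dtypes))}")
        data = np.stack(slices)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if data.dtype not in _ALLOWED_DTYPES:
        raise ValueError(f"unsupported bit depth / dtype: {data.dtype}")
    side = _sidecar(path)
    voxel = 1.0
    meta = {}
    if side.exists():
        info = json.loads(side.read_text())
        voxel = float(info.get("voxel_size_um", 1.0))
        meta = info.get("meta", {})
    return Volume3D(data, voxel, meta)


def save_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write labels as 8-bit TIFF plus a JSON label-name map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.data.astype(np.uint8))
    _sidecar(path).write_text(
        json.dumps({"voxel_size_um": labels.voxel_size_um, "names": labels.names}, indent=1)
    )
    return path


def load_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    info = json.loads(_sidecar(path).read_text())
    return LabelVolume(data.astype(np.uint8), float(info["voxel_size_um"]), dict(info["names"]))
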