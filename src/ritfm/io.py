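"""Readers and writers: multi-page TIFF volumes and columnar field files.

Volumes travel as 32-bit float multi-page TIFF with the voxel pitch stored
in the image description (JSON); a ``.pitch.json`` sidecar is written as
well and used as a fallback when reading files produced elsewhere.  Vector
fields (displacement, traction) travel as headered columnar text (9
significant digits) with a ``.npz`` binary sidecar preserving full
precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .fields import DisplacementField, TractionField
from .volume import Volume

__all__ = [
    "read_volume",
    "write_volume",
    "write_displacement_field",
    "read_displacement_field",
    "write_traction_field",
    "read_traction_field",
    "write_mask",
    "read_mask",
]


def write_volume(vol: Volume, path) -> Path:
    """Write a volume as 32-bit float multi-page TIFF plus pitch sidecar."""
    path = Path(path)
    desc = json.dumps({"voxel_pitch_um": list(vol.pitch), "axes": "ZYX"})
    tifffile.imwrite(path, vol.data.astype(np.float32), description=desc,
                     photometric="minisblack")
    path.with_suffix(path.suffix + ".pitch.json").write_text(desc)
    return path


def read_volume(path, pitch=None) -> Volume:
    """Read a multi-page TIFF volume; pitch from metadata, sidecar or argument.

    Integer inputs are promoted to float with the original dtype recorded.
    Raises a clean error on truncated files or missing pitch.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:  # truncated/corrupt file: no partial Volume
        raise IOError(f"cannot read TIFF volume {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if pitch is None:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            sidecar = path.with_suffix(path.suffix + ".pitch.json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
        pitch = meta.get("voxel_pitch_um")
    if pitch is None:
        raise ValueError(
            f"no voxel pitch for {path}: supply pitch= or add a "
            f"{path.name}.pitch.json sidecar with 'voxel_pitch_um'"
        )
    src_dtype = str(data.dtype)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)
    return Volume(data, tuple(pitch), metadata={"source": str(path),
                                                "source_dtype": src_dtype})


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean mask as an 8-bit TIFF stack."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr > 0


_DISP_HEADER = "x_um y_um depth_um ux_um uy_um uz_um valid quality"
_TRAC_HEADER = "x_um y_um Tx_Pa Ty_Pa Tz_Pa"


def write_displacement_field(field: DisplacementField, path) -> Path:
    """Columnar text (x y z ux uy uz valid quality, micrometres) + npz sidecar."""
    path = Path(path)
    cols = np.column_stack(
        [
            field.coords.reshape(-1, 3),
            field.u.reshape(-1, 3),
            field.valid.reshape(-1, 1).astype(float),
            field.quality.reshape(-1, 1),
        ]
    )
    np.savetxt(path, cols, fmt="%.9e", header=_DISP_HEADER)
    np.savez(
        path.with_suffix(path.suffix + ".npz"),
        u=field.u, coords=field.coords, valid=field.valid,
        quality=field.quality, spacing=np.asarray(field.spacing),
        grid_shape=np.asarray(field.grid_shape),
    )
    return path


def read_displacement_field(path) -> DisplacementField:
    """Read a displacement field; prefers the binary sidecar when present."""
    path = Path(path)
    npz = path.with_suffix(path.suffix + ".npz")
    if npz.exists():
        d = np.load(npz)
        return DisplacementField(
            u=d["u"], coords=d["coords"], valid=d["valid"],
            quality=d["quality"], spacing=tuple(d["spacing"]),
        )
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    if header[:6] != _DISP_HEADER.split()[:6]:
        raise ValueError(
            f"unexpected displacement columns/units in {path}: {header}"
        )
    raw = np.loadtxt(path)
    if raw.shape[1] < 8:
        warnings.warn("no validity column; assuming all nodes valid")
        raw = np.column_stack([raw, np.ones((len(raw), 2))])
    coords, u = raw[:, :3], raw[:, 3:6]
    valid = raw[:, 6] > 0.5
    if np.any(~np.isfinite(u[valid])):
        raise ValueError("NaN displacement vectors not flagged invalid")
    # infer grid shape from unique coordinates (regular grid required)
    xs, ys, zs = (np.unique(coords[:, i]) for i in range(3))
    shape = (zs.size, ys.size, xs.size)
    spacing = tuple(
        float(np.diff(v)[0]) if v.size > 1 else 1.0 for v in (zs, ys, xs)
    )
    return DisplacementField(
        u=u.reshape(shape + (3,)),
        coords=coords.reshape(shape + (3,)),
        valid=valid.reshape(shape),
        quality=raw[:, 7].reshape(shape),
        spacing=spacing,
    )


def write_traction_field(traction: TractionField, path) -> Path:
    """Columnar text (x y Tx Ty Tz, Pa) + npz sidecar."""
    path = Path(path)
    ny, nx = traction.grid_shape
    Y, X = np.meshgrid(
        np.arange(ny) * traction.pitch[0] + traction.origin[0],
        np.arange(nx) * traction.pitch[1] + traction.origin[1],
        indexing="ij",
    )
    cols = np.column_stack([X.ravel(), Y.ravel(), traction.t.reshape(-1, 3)])
    np.savetxt(path, cols, fmt="%.9e", header=_TRAC_HEADER)
    np.savez(
        path.with_suffix(path.suffix + ".npz"),
        t=traction.t, pitch=np.asarray(traction.pitch),
        origin=np.asarray(traction.origin),
    )
    return path


def read_traction_field(path) -> TractionField:
    path = Path(path)
    npz = path.with_suffix(path.suffix + ".npz")
    if npz.exists():
        d = np.load(npz)
        return TractionField(t=d["t"], pitch=tuple(d["pitch"]),
                             origin=tuple(d["origin"]))
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    if header != _TRAC_HEADER.split():
        raise ValueError(f"unexpected traction columns/units in {path}: {header}")
    raw = np.loadtxt(path)
    if np.any(~np.isfinite(raw)):
        raise ValueError("non-finite traction values")
    xs, ys = np.unique(raw[:, 0]), np.unique(raw[:, 1])
    t = raw[:, 2:5].reshape(ys.size, xs.size, 3)
    pitch = tuple(
        float(np.diff(v)[0]) if v.size > 1 else 1.0 for v in (ys, xs)
    )
    return TractionField(t=t, pitch=pitch, origin=(float(ys[0]), float(xs[0])))
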