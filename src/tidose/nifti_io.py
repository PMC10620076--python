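"""NIfTI-1 volume I/O for phantom, field and map volumes (via nibabel)."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .errors import FormatError, GridMismatchError
from .phantom import HeadPhantom


def write_volume(data: np.ndarray, affine: np.ndarray, path,
                 dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 with the given affine."""
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return data, affine


def volume_roundtrip(data: np.ndarray, affine: np.ndarray, path,
                     dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Write then re-read a volume; float32 roundtrips are exact."""
    write_volume(data, affine, path, dtype=dtype)
    return read_volume(path)


def check_same_grid(affine_a: np.ndarray, shape_a, affine_b: np.ndarray,
                    shape_b, atol: float = 1e-6) -> None:
    if tuple(shape_a) != tuple(shape_b) or not np.allclose(
            affine_a, affine_b, atol=atol):
        raise GridMismatchError(
            f"volumes are not on the same grid: shapes {tuple(shape_a)} vs "
            f"{tuple(shape_b)}")


def write_phantom(phantom: HeadPhantom, out_dir) -> dict:
    """Write label, conductivity and brain-mask volumes; returns path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = phantom.affine()
    paths = {}
    for name, data, dt in [
        ("labels", phantom.labels, np.uint8),
        ("conductivity", phantom.conductivity_volume(), np.float32),
        ("brain_mask", phantom.brain_mask, np.uint8),
    ]:
        p = out / f"{name}.nii"
        write_volume(data, aff, p, dtype=dt)
        paths[name] = str(p)
    return paths
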