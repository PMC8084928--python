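"""NIfTI and JSON I/O helpers.

Complex volumes are stored as paired ``*_real.nii.gz`` / ``*_imag.nii.gz``
files because NIfTI complex support is patchy across viewers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_nifti(volume: np.ndarray, spacing_mm, path: str | Path) -> Path:
    """Write a real-valued 3D (or 4D) volume with the given voxel spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(tuple(spacing_mm)))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Return (data, voxel spacing in mm) from a NIfTI file."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def save_complex_nifti(volume: np.ndarray, spacing_mm, stem: str | Path) -> tuple[Path, Path]:
    """Write a complex volume as ``<stem>_real.nii.gz`` and ``<stem>_imag.nii.gz``."""
    stem = Path(stem)
    real = save_nifti(np.real(volume), spacing_mm, stem.parent / f"{stem.name}_real.nii.gz")
    imag = save_nifti(np.imag(volume), spacing_mm, stem.parent / f"{stem.name}_imag.nii.gz")
    return real, imag


def load_complex_nifti(stem: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    stem = Path(stem)
    real, spacing = load_nifti(stem.parent / f"{stem.name}_real.nii.gz")
    imag, _ = load_nifti(stem.parent / f"{stem.name}_imag.nii.gz")
    return real + 1j * imag, spacing


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj: Any) -> Any:  # noqa: D102
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyJSONEncoder) + "\n")
    return path


def load_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
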