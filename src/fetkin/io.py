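"""NIfTI round-trips for dynamic volumes, masks and parameter maps.

The frame schedule travels as a JSON sidecar next to the 4-D image (NIfTI
itself has no reliable per-frame timing slot).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import FrameSchedule

__all__ = [
    "save_dynamic_nifti",
    "load_dynamic_nifti",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_parameter_maps",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_frames.json")
    return path.with_suffix(".json")


def save_dynamic_nifti(path, dynamic: np.ndarray, schedule: FrameSchedule,
                       affine: np.ndarray | None = None) -> None:
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(dynamic, dtype=np.float32), affine), path)
    _sidecar(path).write_text(schedule.to_json())


def load_dynamic_nifti(path):
    path = Path(path)
    img = nib.load(path)
    schedule = FrameSchedule.from_json(_sidecar(path).read_text())
    return np.asarray(img.dataobj, dtype=float), schedule, img.affine


def save_volume_nifti(path, volume: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), Path(path))


def load_volume_nifti(path):
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_parameter_maps(directory, pmap, affine: np.ndarray | None = None) -> list:
    """Write one NIfTI volume per kinetic parameter plus SSR and flag maps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    volumes = dict(pmap.data)
    volumes["ssr"] = pmap.ssr
    volumes["converged"] = pmap.converged.astype(np.float32)
    volumes["at_bound"] = pmap.at_bound.astype(np.float32)
    for name, vol in volumes.items():
        p = directory / f"{pmap.model}_{name}.nii.gz"
        save_volume_nifti(p, vol, affine)
        written.append(p)
    return written
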