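"""NIfTI volume I/O with a JSON sidecar.

Volumes are written as NIfTI-1 with mm spacings in the header (float32 data)
and a sidecar ``<stem>.json`` carrying the radionuclide, the acquisition
time offset and any provenance metadata.  DICOM is deliberately out of
scope; no scanner-private fields are needed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import ActivityVolume, GridSpec


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: ActivityVolume, path: str | Path) -> Path:
    """Write a volume and its sidecar; returns the image path."""
    path = Path(path)
    # storage is (z, y, x); NIfTI wants x fastest
    data = np.ascontiguousarray(vol.values.transpose(2, 1, 0)).astype(np.float32)
    affine = np.diag([*vol.grid.voxel_size, 1.0])
    affine[:3, 3] = vol.grid.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(float(v) for v in vol.grid.voxel_size))
    nib.save(img, str(path))
    sidecar = {
        "radionuclide": vol.radionuclide,
        "time_offset_min": vol.time_offset_min,
        "meta": {k: v for k, v in vol.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_volume(path: str | Path) -> ActivityVolume:
    """Read a NIfTI volume (3D, mm spacings required) and its sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z is None or not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError("image header is missing positive mm voxel spacings")
    origin = img.affine[:3, 3]
    grid = GridSpec(voxel_size=zooms, dims=data.shape, origin=origin)
    radionuclide, offset, meta = "none", 0.0, {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        radionuclide = side.get("radionuclide", "none")
        offset = float(side.get("time_offset_min", 0.0))
        meta = side.get("meta", {})
    return ActivityVolume(values=np.asarray(data, dtype=float).transpose(2, 1, 0),
                          grid=grid, radionuclide=radionuclide,
                          time_offset_min=offset, meta=meta)
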