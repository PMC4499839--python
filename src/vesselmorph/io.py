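"""Volume and table I/O.

TIFF stacks are handled by :mod:`tifffile`, NRRD by SimpleITK.  Axis
order on disk follows the in-memory NumPy convention (page/slice axis
first for TIFF).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def read_volume(path: str | Path) -> np.ndarray:
    """Read a 3D volume from a multi-page TIFF or an NRRD file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)))
    elif suffix in (".nrrd", ".nhdr"):
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    return arr


def write_volume(path: str | Path, volume: np.ndarray) -> None:
    """Write a 3D volume as multi-page TIFF or NRRD, chosen by suffix."""
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), volume, photometric="minisblack")
    elif suffix in (".nrrd", ".nhdr"):
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(volume), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")


def write_label_map(path: str | Path, labels: np.ndarray, semantics: dict) -> None:
    """Write a uint8 label volume plus a JSON sidecar naming the labels."""
    path = Path(path)
    write_volume(path, labels.astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"labels": semantics}, indent=2))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
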