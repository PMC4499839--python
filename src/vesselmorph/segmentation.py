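"""Threshold-based lumen/wall segmentation with scripted manual edits.

The vessel wall and lumen are extracted from the grayscale volume by
binning voxels into intensity intervals, followed by morphological
refinement (opening/closing, largest-component retention, hole
filling).  Manual corrections — the reproducible analogue of slice-wise
hand editing — enter as :class:`EditScript` files: ordered polygon
edits applied to named slices, so a segmentation run is fully auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["LABELS", "WallLabelMap", "Edit", "EditScript",
           "EmptySegmentationWarning", "segment_vessel", "apply_edits",
           "component_volume"]

LABELS = {"background": 0, "parenchyma": 1, "lumen": 2, "wall": 3, "plaque": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: 26-connectivity structuring element for component labelling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySegmentationWarning(UserWarning):
    """No lumen voxels were found; the label map may be unusable."""


class EditError(ValueError):
    """An edit in an EditScript is invalid; names the edit ordinal."""


@dataclass
class WallLabelMap:
    """Integer label volume (see :data:`LABELS`) with its voxel size."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def is_empty(self) -> bool:
        return not bool((self.labels == LABELS["lumen"]).any())

    def counts(self) -> dict:
        return {name: int((self.labels == code).sum())
                for name, code in LABELS.items()}


@dataclass
class Edit:
    """One polygon edit on a slice.

    ``axis``/``index`` name the slice; ``polygon`` is (M, 2) vertices in
    the in-plane voxel coordinates (remaining axes in order); ``action``
    is ``"set"`` (paint ``label``) or ``"clear"`` (reset to background).
    """

    axis: int
    index: int
    polygon: np.ndarray
    label: int
    action: str = "set"

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 \
                or len(self.polygon) < 3:
            raise EditError("polygon must be (M>=3, 2) vertices")
        if self.action not in ("set", "clear"):
            raise EditError(f"unknown action {self.action!r}")


@dataclass
class EditScript:
    edits: list[Edit] = field(default_factory=list)

    @classmethod
    def from_json_obj(cls, obj) -> "EditScript":
        edits = [Edit(axis=e["axis"], index=e["index"],
                      polygon=np.asarray(e["polygon"], float),
                      label=e["label"], action=e.get("action", "set"))
                 for e in obj]
        return cls(edits)

    def to_json_obj(self):
        return [{"axis": e.axis, "index": e.index,
                 "polygon": e.polygon.tolist(), "label": e.label,
                 "action": e.action} for e in self.edits]


def _largest_component(mask: np.ndarray, seed_vox=None) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        return np.zeros_like(mask)
    if seed_vox is not None:
        code = lab[tuple(int(round(c)) for c in seed_vox)]
        if code == 0:
            return np.zeros_like(mask)
        return lab == code
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def segment_vessel(volume: np.ndarray, thresholds, morph_radius: int = 0,
                   class_order=("background", "lumen", "parenchyma", "wall"),
                   lumen_seed_vox=None, voxel_size_um: float = 1.0
                   ) -> WallLabelMap:
    """Segment a volume into background/parenchyma/lumen/wall labels.

    Parameters
    ----------
    thresholds : sequence of float, strictly increasing
        Bin edges; bin ``i`` (``thresholds[i-1] <= v < thresholds[i]``)
        gets the class ``class_order[i]``.
    morph_radius : int
        Radius (voxels) of the opening/closing ball applied to the lumen
        and wall masks; 0 disables morphology.
    class_order : sequence of label names, one per bin
        Default matches soft-tissue phase contrast where
        background < lumen < parenchyma < wall in intensity.
    lumen_seed_vox : optional voxel index
        When given, the lumen component containing this seed is kept;
        otherwise the largest 26-connected component.

    Notes
    -----
    Refinement: morphological opening then closing; retention of one
    26-connected lumen component; 6-connected hole filling of the lumen;
    the wall class is restricted to wall-bin voxels 26-connected to the
    lumen shell.
    """
    volume = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if len(class_order) != len(thresholds) + 1:
        raise ValueError("need len(thresholds)+1 class names")
    vmin, vmax = volume.min(), volume.max()
    if thresholds.min() > vmax or thresholds.max() < vmin:
        warnings.warn("thresholds fall outside the volume intensity range; "
                      "some classes will be empty", UserWarning,
                      stacklevel=2)

    bins = np.digitize(volume, thresholds)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    for i, name in enumerate(class_order):
        labels[bins == i] = LABELS[name]

    lumen = labels == LABELS["lumen"]
    wall = labels == LABELS["wall"]
    if morph_radius >= 1:
        ball = _ball(morph_radius)
        lumen = ndimage.binary_closing(
            ndimage.binary_opening(lumen, structure=ball), structure=ball)
        # closing only for the wall: opening would erase a shell whose
        # thickness is comparable to the structuring radius
        wall = ndimage.binary_closing(wall, structure=ball)

    lumen = _largest_component(lumen, lumen_seed_vox)
    # 6-connected hole filling (default structure of binary_fill_holes)
    lumen = ndimage.binary_fill_holes(lumen)

    if not lumen.any():
        warnings.warn("no lumen component found — empty segmentation",
                      EmptySegmentationWarning, stacklevel=2)
    else:
        # wall voxels must be 26-connected to the lumen shell
        shell = ndimage.binary_dilation(lumen, structure=STRUCT_26) & ~lumen
        wlab, wn = ndimage.label(wall, structure=STRUCT_26)
        if wn:
            touching = np.unique(wlab[shell & (wlab > 0)])
            wall = np.isin(wlab, touching[touching > 0])

    out = labels.copy()
    out[(labels == LABELS["lumen"]) | (labels == LABELS["wall"])] = \
        LABELS["parenchyma"]
    out[wall] = LABELS["wall"]
    out[lumen] = LABELS["lumen"]
    return WallLabelMap(out, voxel_size_um=voxel_size_um)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.indices((2 * r + 1,) * 3) - r
    return (g ** 2).sum(axis=0) <= r ** 2


def apply_edits(label_map: WallLabelMap, script: EditScript) -> WallLabelMap:
    """Apply an ordered polygon edit script; deterministic and idempotent.

    Voxels whose centres fall inside each polygon on the named slice are
    set to the edit's label (``set``) or to background (``clear``).
    """
    from matplotlib.path import Path as MplPath

    out = label_map.labels.copy()
    for ordinal, e in enumerate(script.edits):
        if not 0 <= e.axis <= 2:
            raise EditError(f"edit {ordinal}: axis {e.axis} out of range")
        if not 0 <= e.index < out.shape[e.axis]:
            raise EditError(
                f"edit {ordinal}: slice index {e.index} out of range for "
                f"axis {e.axis} (size {out.shape[e.axis]})")
        plane_axes = [a for a in range(3) if a != e.axis]
        ny, nx = out.shape[plane_axes[0]], out.shape[plane_axes[1]]
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        inside = MplPath(e.polygon).contains_points(pts).reshape(ny, nx)
        sl = [slice(None)] * 3
        sl[e.axis] = e.index
        plane = out[tuple(sl)]
        value = e.label if e.action == "set" else LABELS["background"]
        plane[inside] = value
        out[tuple(sl)] = plane
    return WallLabelMap(out, label_map.voxel_size_um)


def component_volume(label_map: WallLabelMap, label: int) -> float:
    """Volume of one label in nanolitres (1 nL = 1e6 um^3)."""
    count = int((label_map.labels == label).sum())
    if count == 0:
        warnings.warn(f"label {label} absent from map; volume is 0 nL",
                      UserWarning, stacklevel=2)
    return count * label_map.voxel_size_um ** 3 * 1e-6
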