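"""Synthetic vessel phantoms with exact geometric ground truth.

A phantom is a set of tubular branches (swept circles along polylines,
radius and wall thickness linearly interpolated between control points)
embedded in an ellipsoidal parenchyma envelope surrounded by empty
background.  Optional focal plaques thicken the wall over an arc-length
interval.  The generator returns the grayscale volume together with
truth labels, the truth centerline and a truth thickness table, so every
downstream stage (filtering, segmentation, centerline, morphometry) can
be validated by parameter recovery.

Intensities are in arbitrary units; :func:`calibrate_intensities` maps
target SNRs (signal mean over background-noise SD) to intensity levels
so a corrupted phantom reproduces given SNRs in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centerline import Branch, CenterlineTree
from .segmentation import LABELS, WallLabelMap

__all__ = [
    "BranchSpec", "PlaqueSpec", "ArtifactParams", "PhantomSpec",
    "PhantomBundle", "generate_phantom", "corrupt_volume",
    "calibrate_intensities",
]

#: default intensity levels, arbitrary units (ordering background <
#: lumen < parenchyma < wall < plaque mirrors soft-tissue phase contrast;
#: the background emulates the agarose embedding gel, whose refractive
#: index decrement is close to soft tissue, not vacuum)
DEFAULT_INTENSITIES = {
    "background": 110.0,
    "parenchyma": 134.2,
    "lumen": 120.1,
    "wall": 139.7,
    "plaque": 145.0,
}


class GeometryError(ValueError):
    """Phantom geometry violates the volume bounds or clearance rules."""


@dataclass
class BranchSpec:
    """One tubular branch.

    Parameters
    ----------
    points_um : (N, 3) array
        Polyline control points in micrometres, NumPy axis order.
    inner_radius_um : float or (N,) array
        Lumen radius at each control point (scalars broadcast).
    wall_thickness_um : float or (N,) array
        Wall thickness at each control point.
    """

    points_um: np.ndarray
    inner_radius_um: float | np.ndarray
    wall_thickness_um: float | np.ndarray

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, dtype=float)
        n = len(self.points_um)
        self.inner_radius_um = np.broadcast_to(
            np.asarray(self.inner_radius_um, dtype=float), (n,)).copy()
        self.wall_thickness_um = np.broadcast_to(
            np.asarray(self.wall_thickness_um, dtype=float), (n,)).copy()


@dataclass
class PlaqueSpec:
    """Focal wall thickening on a branch over an arc-length interval."""

    branch: int
    arc_start_um: float
    arc_stop_um: float
    extra_thickness_um: float


@dataclass
class ArtifactParams:
    """Stripe and ring artifact description.

    Stripes are column-constant offsets within each slice (constant
    along axis 1, indexed by axis 2); rings are concentric Gaussian
    annular offsets around ``center_vox`` in the (axis1, axis2) plane,
    identical in every slice along axis 0.
    """

    stripe_columns: tuple[int, ...] = ()
    stripe_amplitudes: tuple[float, ...] = ()
    ring_radii_vox: tuple[float, ...] = ()
    ring_amplitudes: tuple[float, ...] = ()
    ring_width_vox: float = 1.0
    center_vox: tuple[float, float] | None = None


@dataclass
class PhantomSpec:
    """Full phantom description; see module docstring for the model."""

    shape: tuple[int, int, int]
    branches: list[BranchSpec]
    voxel_size_um: float = 7.4
    plaques: list[PlaqueSpec] = field(default_factory=list)
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    envelope_center_um: np.ndarray | None = None
    envelope_radii_um: np.ndarray | None = None
    noise_sd: float = 0.0
    artifacts: ArtifactParams | None = None
    rng_seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        extent = np.asarray(self.shape, dtype=float) * self.voxel_size_um
        if self.envelope_center_um is None:
            self.envelope_center_um = extent / 2.0
        if self.envelope_radii_um is None:
            self.envelope_radii_um = 0.47 * extent
        self.envelope_center_um = np.asarray(self.envelope_center_um, float)
        self.envelope_radii_um = np.asarray(self.envelope_radii_um, float)

    def validate(self) -> None:
        if self.voxel_size_um <= 0:
            raise GeometryError("voxel_size must be positive")
        if not self.branches:
            raise GeometryError("phantom needs at least one branch")
        extent = np.asarray(self.shape, float) * self.voxel_size_um
        for i, br in enumerate(self.branches):
            if np.any(br.inner_radius_um <= 0):
                raise GeometryError(f"branch {i}: inner radius must be > 0")
            if np.any(br.wall_thickness_um <= 0):
                raise GeometryError(f"branch {i}: wall thickness must be > 0")
            outer = br.inner_radius_um + br.wall_thickness_um
            lo = br.points_um - outer[:, None]
            hi = br.points_um + outer[:, None]
            if np.any(lo < 0) or np.any(hi > extent):
                raise GeometryError(
                    f"branch {i} exits the volume (clearance must be >= "
                    "outer radius on every axis)")
        for p in self.plaques:
            if not 0 <= p.branch < len(self.branches):
                raise GeometryError(f"plaque references unknown branch {p.branch}")
            if p.extra_thickness_um <= 0 or p.arc_stop_um <= p.arc_start_um:
                raise GeometryError("plaque interval/thickness invalid")


@dataclass
class PhantomBundle:
    """Generated phantom: image, truth labels, centerline, thickness."""

    volume: np.ndarray
    truth_labels: WallLabelMap
    truth_centerline: CenterlineTree
    truth_thickness: pd.DataFrame  # branch_id, arc_um, thickness_um
    spec: PhantomSpec


def _densify_branch(br: BranchSpec, step_um: float):
    """Resample a branch polyline at ~step_um with interpolated profiles.

    Returns (points (M,3), arcs (M,), r_in (M,), t_wall (M,)).
    """
    pts = br.points_um
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg)])
    total = arcs[-1]
    if total <= 0:
        raise GeometryError("degenerate branch polyline (zero length)")
    n = max(int(np.ceil(total / step_um)) + 1, 2)
    s = np.linspace(0.0, total, n)
    dense = np.column_stack([np.interp(s, arcs, pts[:, k]) for k in range(3)])
    r_in = np.interp(s, arcs, br.inner_radius_um)
    t_wall = np.interp(s, arcs, br.wall_thickness_um)
    return dense, s, r_in, t_wall


def _branch_fields(spec: PhantomSpec, step_um: float):
    """Dense samples for all branches with plaque increments applied."""
    out = []
    for bi, br in enumerate(spec.branches):
        dense, s, r_in, t_wall = _densify_branch(br, step_um)
        extra = np.zeros_like(s)
        for p in spec.plaques:
            if p.branch == bi:
                sel = (s >= p.arc_start_um) & (s <= p.arc_stop_um)
                extra[sel] = np.maximum(extra[sel], p.extra_thickness_um)
        out.append((dense, s, r_in, t_wall, extra))
    return out


def _classify_points(points_um, fields, voxel_size):
    """Tissue class of arbitrary world points against the tube geometry.

    Returns int codes: 0 none, 2 lumen, 3 wall, 4 plaque (LABELS codes).
    Lumen takes precedence over wall over plaque across branches.  Tubes
    have flat end caps: points axially beyond a branch end do not belong
    to it.
    """
    n = len(points_um)
    cls = np.zeros(n, dtype=np.uint8)
    rank = np.zeros(n, dtype=np.int8)  # plaque=1 < wall=2 < lumen=3
    for dense, s, r_in, t_wall, extra in fields:
        tree = cKDTree(dense)
        r_out = r_in + t_wall + extra
        ub = r_out.max() + voxel_size
        d, idx = tree.query(points_um, distance_upper_bound=ub, workers=-1)
        hit = np.isfinite(d)
        if not hit.any():
            continue
        hi = idx[hit]
        dh = d[hit].copy()
        # flat caps: drop points beyond the ends, use radial distance there
        for end_i, tan in ((0, dense[1] - dense[0]),
                           (len(dense) - 1, dense[-1] - dense[-2])):
            at_end = hi == end_i
            if not at_end.any():
                continue
            tan = tan / np.linalg.norm(tan)
            ax = (points_um[hit][at_end] - dense[end_i]) @ tan
            beyond = ax < 0 if end_i == 0 else ax > 0
            rad = np.sqrt(np.clip(dh[at_end] ** 2 - ax ** 2, 0.0, None))
            new_d = np.where(beyond, np.inf, rad)
            dh[at_end] = new_d
        lum = dh < r_in[hi]
        wal = ~lum & (dh < r_in[hi] + t_wall[hi])
        plq = ~lum & ~wal & (dh < r_out[hi])
        sub_rank = np.zeros(hit.sum(), dtype=np.int8)
        sub_cls = np.zeros(hit.sum(), dtype=np.uint8)
        sub_rank[plq], sub_cls[plq] = 1, LABELS["plaque"]
        sub_rank[wal], sub_cls[wal] = 2, LABELS["wall"]
        sub_rank[lum], sub_cls[lum] = 3, LABELS["lumen"]
        better = sub_rank > rank[hit]
        take = np.flatnonzero(hit)[better]
        cls[take] = sub_cls[better]
        rank[take] = sub_rank[better]
    return cls


def generate_phantom(spec: PhantomSpec, supersample: int = 1) -> PhantomBundle:
    """Rasterize a phantom.

    Truth labels always use a crisp voxel-centre test.  With
    ``supersample`` > 1 the grayscale rendering averages ``supersample**3``
    sub-voxel intensity samples for voxels near the tube surfaces,
    emulating partial-volume edges while the truth stays exact.
    """
    spec.validate()
    vox = spec.voxel_size_um
    fields = _branch_fields(spec, step_um=vox / 4.0)

    idx = np.indices(spec.shape, dtype=float)
    centers = (idx + 0.5).reshape(3, -1).T * vox

    cls = _classify_points(centers, fields, vox)

    # parenchyma inside the ellipsoid envelope, background outside
    rel = (centers - spec.envelope_center_um) / spec.envelope_radii_um
    inside_env = (rel ** 2).sum(axis=1) <= 1.0
    labels = np.where(inside_env, LABELS["parenchyma"], LABELS["background"])
    labels = labels.astype(np.uint8)
    tissue = cls > 0
    labels[tissue] = cls[tissue]
    labels3d = labels.reshape(spec.shape)

    level_of = np.zeros(5)
    for name, code in LABELS.items():
        level_of[code] = spec.intensities[name]
    volume = level_of[labels3d]

    if supersample > 1:
        volume = _supersample_render(
            volume, labels3d, spec, fields, level_of, supersample)

    truth_labels = WallLabelMap(labels3d, vox)
    truth_centerline = _truth_centerline(spec)
    truth_thickness = _truth_thickness(spec, fields)
    return PhantomBundle(volume, truth_labels, truth_centerline,
                         truth_thickness, spec)


def _supersample_render(volume, labels3d, spec, fields, level_of, ss):
    """Re-render voxels near tube surfaces by sub-voxel averaging."""
    vox = spec.voxel_size_um
    # voxels whose centre lies within 1.5 voxels of an inner/outer surface
    idx = np.indices(spec.shape, dtype=float)
    centers = (idx + 0.5).reshape(3, -1).T * vox
    near = np.zeros(len(centers), dtype=bool)
    for dense, s, r_in, t_wall, extra in fields:
        tree = cKDTree(dense)
        r_out = r_in + t_wall + extra
        ub = r_out.max() + 2 * vox
        d, i = tree.query(centers, distance_upper_bound=ub, workers=-1)
        hit = np.isfinite(d)
        hi = i[hit]
        band = 1.5 * vox
        surf = (np.abs(d[hit] - r_in[hi]) < band) | \
               (np.abs(d[hit] - (r_in[hi] + t_wall[hi])) < band) | \
               (np.abs(d[hit] - r_out[hi]) < band)
        near[np.flatnonzero(hit)[surf]] = True
    if not near.any():
        return volume
    sel = centers[near]
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"),
                   axis=-1).reshape(-1, 3) * vox
    acc = np.zeros(len(sel))
    env_c, env_r = spec.envelope_center_um, spec.envelope_radii_um
    for o in sub:
        pts = sel + o
        c = _classify_points(pts, fields, vox)
        rel = (pts - env_c) / env_r
        base = np.where((rel ** 2).sum(axis=1) <= 1.0,
                        LABELS["parenchyma"], LABELS["background"])
        code = np.where(c > 0, c, base)
        acc += level_of[code]
    out = volume.reshape(-1).copy()
    out[near] = acc / len(sub)
    return out.reshape(volume.shape)


def _truth_centerline(spec: PhantomSpec) -> CenterlineTree:
    branches = []
    for bi, br in enumerate(spec.branches):
        depth = 0 if bi == 0 else 1
        branches.append(Branch(points_um=br.points_um.copy(), depth=depth,
                               branch_id=bi))
    root = spec.branches[0].points_um[0].copy()
    return CenterlineTree(branches=branches, root_um=root,
                          voxel_size_um=spec.voxel_size_um)


def _truth_thickness(spec: PhantomSpec, fields) -> pd.DataFrame:
    rows = []
    step = spec.voxel_size_um
    for bi, (dense, s, r_in, t_wall, extra) in enumerate(fields):
        arcs = np.arange(0.0, s[-1] + 1e-9, step)
        thick = np.interp(arcs, s, t_wall + extra)
        for a, t in zip(arcs, thick):
            rows.append((bi, a, t))
    return pd.DataFrame(rows, columns=["branch_id", "arc_um", "thickness_um"])


def occupancy_fields(spec: PhantomSpec, supersample: int = 4):
    """Partial-volume occupancy fields for sub-voxel morphometry oracles.

    Returns :class:`~vesselmorph.morphometry.IndicatorFields` whose
    ``lumen`` and ``vessel`` arrays hold the fraction of each voxel
    inside the inner / outer tube surface, estimated from
    ``supersample**3`` sub-voxel centre tests (only voxels near a
    surface are refined; the rest stay crisp 0/1).
    """
    from .morphometry import IndicatorFields

    spec.validate()
    vox = spec.voxel_size_um
    fields = _branch_fields(spec, step_um=vox / 4.0)
    idx = np.indices(spec.shape, dtype=float)
    centers = (idx + 0.5).reshape(3, -1).T * vox
    cls = _classify_points(centers, fields, vox)
    lum = (cls == LABELS["lumen"]).astype(np.float64)
    ves = (cls >= LABELS["lumen"]).astype(np.float64)

    near = np.zeros(len(centers), dtype=bool)
    for dense, s, r_in, t_wall, extra in fields:
        tree = cKDTree(dense)
        r_out = r_in + t_wall + extra
        ub = r_out.max() + 2 * vox
        d, i = tree.query(centers, distance_upper_bound=ub, workers=-1)
        hit = np.isfinite(d)
        hi = i[hit]
        band = 1.5 * vox
        surf = (np.abs(d[hit] - r_in[hi]) < band) | \
               (np.abs(d[hit] - r_out[hi]) < band)
        near[np.flatnonzero(hit)[surf]] = True
    if near.any():
        sel = centers[near]
        offs = (np.arange(supersample) + 0.5) / supersample - 0.5
        sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"),
                       axis=-1).reshape(-1, 3) * vox
        acc_l = np.zeros(len(sel))
        acc_v = np.zeros(len(sel))
        for o in sub:
            c = _classify_points(sel + o, fields, vox)
            acc_l += c == LABELS["lumen"]
            acc_v += c >= LABELS["lumen"]
        lum[near] = acc_l / len(sub)
        ves[near] = acc_v / len(sub)
    return IndicatorFields(lumen=lum.reshape(spec.shape),
                           vessel=ves.reshape(spec.shape),
                           voxel_size_um=vox)


def corrupt_volume(volume: np.ndarray, noise_sd: float,
                   artifacts: ArtifactParams | None = None,
                   rng_seed: int = 0) -> np.ndarray:
    """Add Gaussian noise plus stripe/ring artifacts (deterministic per seed)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = np.asarray(volume, dtype=float).copy()
    if artifacts is not None:
        if len(artifacts.stripe_columns) != len(artifacts.stripe_amplitudes):
            raise ValueError("stripe columns/amplitudes length mismatch")
        for col, amp in zip(artifacts.stripe_columns,
                            artifacts.stripe_amplitudes):
            out[:, :, int(col)] += amp
        if artifacts.ring_radii_vox:
            c = artifacts.center_vox
            if c is None:
                c = ((out.shape[1] - 1) / 2.0, (out.shape[2] - 1) / 2.0)
            yy, xx = np.meshgrid(np.arange(out.shape[1], dtype=float),
                                 np.arange(out.shape[2], dtype=float),
                                 indexing="ij")
            r = np.hypot(yy - c[0], xx - c[1])
            ring = np.zeros_like(r)
            w = artifacts.ring_width_vox
            for rad, amp in zip(artifacts.ring_radii_vox,
                                artifacts.ring_amplitudes):
                ring += amp * np.exp(-0.5 * ((r - rad) / w) ** 2)
            out += ring[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


def calibrate_intensities(target_snrs: dict, noise_sd: float) -> dict:
    """Intensity levels S = SNR_target * noise_sd per tissue class."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return {name: float(snr) * noise_sd for name, snr in target_snrs.items()}
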