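"""Combined wavelet-Fourier removal of stripe and ring artifacts.

Stripes (offsets constant along one image axis) concentrate, level by
level, in one detail band of a multilevel wavelet decomposition; there
they are constant along the stripe axis, i.e. their energy sits at zero
frequency of a 1D Fourier transform taken along that axis.  Damping
those frequencies with ``g(k) = 1 - exp(-k^2 / (2 sigma^2))`` and
reconstructing removes the stripes while leaving genuine image detail
(which is not axis-constant) almost untouched.

Ring artifacts in reconstructed slices are stripes in polar
coordinates: the slice is resampled around the rotation centre, the
stripe filter applied along the angular axis, and the result mapped
back; pixels outside the inscribed disk pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["FilterConfig", "stripe_filter", "ring_filter", "destripe_volume"]


@dataclass
class FilterConfig:
    """Wavelet-Fourier filter parameters.

    ``wavelet``/``levels``/``sigma`` control the decomposition and the
    frequency damping width (in frequency-index units).  ``mode`` picks
    plain stripe removal or the polar ring detour; ``center`` is the
    rotation centre in slice pixel coordinates (defaults to the slice
    centre); ``slice_axis`` is the volume axis to iterate over.
    """

    wavelet: str = "db4"
    levels: int = 4
    sigma: float = 2.0
    mode: str = "ring"
    center: tuple[float, float] | None = None
    slice_axis: int = 0

    def validate(self, image_shape) -> None:
        if self.sigma <= 0:
            raise ValueError("damping sigma must be > 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        max_l = int(np.floor(np.log2(min(image_shape))))
        if self.levels > max_l:
            raise ValueError(
                f"levels={self.levels} too large for image {image_shape} "
                f"(max {max_l})")
        if self.mode not in ("stripe", "ring", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _damp(coeff: np.ndarray, sigma: float) -> np.ndarray:
    """Damp frequencies near zero along axis 0 of a detail band."""
    n = coeff.shape[0]
    f = np.fft.fft(coeff, axis=0)
    k = np.fft.fftfreq(n) * n  # integer-valued frequency index
    g = 1.0 - np.exp(-(k ** 2) / (2.0 * sigma ** 2))
    f *= g[:, None]
    return np.real(np.fft.ifft(f, axis=0))


def stripe_filter(image: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Remove stripes that are constant along image axis 0.

    Each column (axis-1 index) may carry a near-constant offset; the
    filter damps exactly that component.  The output has the input's
    shape; its mean can differ from the input's only through the damped
    detail bands.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    config.validate(image.shape)
    with warnings.catch_warnings():
        # symmetric padding handles the boundary; pywt's blanket warning
        # about deep levels is not actionable here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(image, config.wavelet, mode="symmetric",
                               level=config.levels)
    new = [coeffs[0]]
    for (cH, cV, cD) in coeffs[1:]:
        # axis-0-constant patterns varying along axis 1 land in cV
        new.append((cH, _damp(cV, config.sigma), cD))
    out = pywt.waverec2(new, config.wavelet, mode="symmetric")
    return out[: image.shape[0], : image.shape[1]]


def _polar_grid(shape, center):
    c0, c1 = center
    r_max = min(c0, c1, shape[0] - 1 - c0, shape[1] - 1 - c1)
    # unit arc spacing at the rim (Nyquist for voxel-scale detail)
    n_theta = int(np.ceil(2.0 * np.pi * r_max))
    radii = np.arange(0.0, r_max + 0.5, 0.5)
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    return r_max, radii, thetas


def ring_filter(slice2d: np.ndarray, config: FilterConfig) -> np.ndarray:
    """Remove concentric ring offsets around the rotation centre.

    The slice is resampled to polar coordinates (angle on axis 0, so
    rings become axis-0-constant stripes), stripe-filtered, and mapped
    back inside the inscribed disk.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    center = config.center
    if center is None:
        center = ((slice2d.shape[0] - 1) / 2.0, (slice2d.shape[1] - 1) / 2.0)
    if not (0 <= center[0] <= slice2d.shape[0] - 1
            and 0 <= center[1] <= slice2d.shape[1] - 1):
        raise ValueError(f"rotation centre {center} outside slice "
                         f"{slice2d.shape}")
    r_max, radii, thetas = _polar_grid(slice2d.shape, center)
    if r_max < 4:
        return slice2d.copy()

    rr, tt = np.meshgrid(radii, thetas, indexing="xy")  # (n_theta, n_r)
    y = center[0] + rr * np.cos(tt)
    x = center[1] + rr * np.sin(tt)
    polar = ndimage.map_coordinates(slice2d, [y.ravel(), x.ravel()],
                                    order=3, mode="nearest")
    polar = polar.reshape(len(thetas), len(radii))

    sub = FilterConfig(wavelet=config.wavelet, levels=config.levels,
                       sigma=config.sigma, mode="stripe")
    max_l = int(np.floor(np.log2(min(polar.shape))))
    if sub.levels > max_l:
        warnings.warn(f"reducing wavelet levels to {max_l} for polar image "
                      f"{polar.shape}", UserWarning, stacklevel=2)
        sub.levels = max_l
    # only the additive ring correction round-trips through polar space,
    # so resampling blur never touches the underlying image
    correction = stripe_filter(polar, sub) - polar

    # map back: wrap the angular axis by appending the first row
    polar_pad = np.vstack([correction, correction[:1]])
    yy, xx = np.meshgrid(np.arange(slice2d.shape[0], dtype=float),
                         np.arange(slice2d.shape[1], dtype=float),
                         indexing="ij")
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dx, dy), 2 * np.pi)
    inside = r <= r_max - 1.0
    ti = theta[inside] / (2 * np.pi) * len(thetas)
    ri = r[inside] / 0.5
    vals = ndimage.map_coordinates(polar_pad, [ti, ri], order=3,
                                   mode="nearest")
    out = slice2d.copy()
    out[inside] += vals
    return out


def destripe_volume(volume: np.ndarray, config: FilterConfig,
                    return_log: bool = False):
    """Apply the ring (or stripe) filter slice-by-slice along an axis."""
    volume = np.asarray(volume, dtype=float)
    axis = config.slice_axis
    out = np.empty_like(volume)
    log = []
    if config.mode == "ring":
        filt = ring_filter
    elif config.mode == "stripe":
        filt = stripe_filter
    else:  # combined: in-slice stripes first, then the polar ring pass
        def filt(plane, cfg):
            return ring_filter(stripe_filter(plane, cfg), cfg)
    for i in range(volume.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = i
        plane = volume[tuple(sl)]
        try:
            fplane = filt(plane, config)
        except Exception as exc:
            raise RuntimeError(f"filter failed on slice {i} along axis "
                               f"{axis}: {exc}") from exc
        out[tuple(sl)] = fplane
        denom = np.linalg.norm(plane) or 1.0
        log.append({"slice": i,
                    "rel_change": float(np.linalg.norm(fplane - plane)
                                        / denom)})
    if return_log:
        return out, log
    return out
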