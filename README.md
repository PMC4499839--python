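# vesselmorph

3D vascular morphometry for synchrotron phase-contrast volumes of
small-animal hearts: artifact filtering, vessel wall segmentation,
centerline-based wall-thickness measurement, per-segment statistics,
and ROI-based image-quality metrics — with a synthetic vessel-phantom
generator providing exact ground truth for every stage.

It is written for imaging scientists who need reproducible wall-
thickness numbers from reconstructed micro-CT/DPC volumes (and for
anyone validating such a pipeline without access to beamline data).

## The measurement

For a segmented coronary artery the lumen centerline is extracted as a
minimal-cost path tree (edge cost ∝ 1/(distance transform + ε)) and
resampled in equidistant steps of 22.2 µm.  At each point a plane
perpendicular to the centerline intersects the inner and outer wall
surfaces; each contour's area *A* gives an equivalent radius

    r = √(A / π)

and the local wall thickness is *r*<sub>out</sub> − *r*<sub>in</sub>.
Thickness values are grouped into proximal/mid/distal segments of the
main artery and of the side branches and reported as *n*, mean ± SD.
Image quality uses SNR = S/N and CNR = (S₁ − S₂)/N, with N the standard
deviation of an empty background region; groups are compared with
unpaired two-tailed Student's t-tests (pooled variance).

Ring and stripe artifacts are removed with a combined wavelet–Fourier
filter: stripe energy is damped at each wavelet level with
g(k) = 1 − exp(−k²/2σ²) along the stripe axis; rings are handled by a
polar detour around the rotation centre in which only the additive
correction round-trips the resampling.

## Worked example

```python
import numpy as np
from vesselmorph import (BranchSpec, PhantomSpec, generate_phantom,
                         segment_vessel, extract_centerline,
                         resample_centerline, label_segments,
                         wall_thickness_profile, segment_summary,
                         GridConfig)

vox = 7.4                      # um, isotropic
c = 32.5 * vox                 # tube axis through voxel centres
axis = np.array([[12 * vox, c, c], [108 * vox, c, c]])
spec = PhantomSpec(shape=(120, 64, 64),
                   branches=[BranchSpec(axis, inner_radius_um=50.0,
                                        wall_thickness_um=30.0)],
                   voxel_size_um=vox)
bundle = generate_phantom(spec)

labels = segment_vessel(bundle.volume, [115.05, 127.15, 136.95],
                        voxel_size_um=vox)
tree = extract_centerline(labels.mask("lumen"), vox,
                          root_seed_um=axis[0] + [vox, 0, 0])
sampled = label_segments(resample_centerline(tree, step_um=22.2))
profile = wall_thickness_profile(labels, sampled,
                                 GridConfig(half_width_um=130))
print(segment_summary(profile, min_n=9).to_string(index=False))
```

prints

```
segment_class  n   mean_um  sd_um  low_n
  distal main  9 29.511592    0.0  False
     mid main  9 29.511592    0.0  False
proximal main  9 29.511592    0.0  False
```

— 27 cross-sections along a 577 µm extracted centerline, each
recovering the true 30 µm wall to within half a voxel (the residual
0.49 µm offset is the half-voxel surface quantisation of a binary
label map; fractional occupancy fields via `occupancy_fields` reduce
it further).

The same chain is scriptable from the shell:

```sh
vesselmorph run --config run.yaml --out results/
vesselmorph destripe in.tif out.tif --mode ring --levels 5 --sigma 0.5
```

`run` executes phantom → corrupt → destripe → segment → centerline →
measure → stats per a single YAML config, writing every intermediate
artifact plus a manifest with SHA-256 checksums; identical config and
seed reproduce bit-identical outputs.

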