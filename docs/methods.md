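# Methods

`vesselmorph` quantifies coronary-artery wall thickness in reconstructed
3D phase-contrast volumes of small-animal hearts.  This note documents
the models, the numerical choices, and what the synthetic phantoms do
and do not emulate.

## Measurement model

The vessel wall is the tissue shell between the lumen and the
surrounding myocardial parenchyma.  The measurement chain is:

1. **Artifact removal.** Reconstructed slices carry concentric ring
   artifacts (detector nonuniformity around the rotation centre) and
   column-constant stripes.  Both are removed with a combined
   wavelet–Fourier filter (see below).
2. **Segmentation.** Voxels are binned by intensity thresholds into
   background / lumen / parenchyma / wall, then refined morphologically.
   Manual corrections enter only as polygon *edit scripts*, so every
   run is reproducible and auditable.
3. **Centerline.** The lumen centerline is a minimal-cost path tree over
   the 26-connected lumen voxel graph with edge cost
   `step · 1/(DT + ε)` (`DT` = Euclidean distance transform, ε = 0.5
   voxel), which concentrates paths on the medial axis the way flow
   concentrates in the middle of a channel.  An optional harmonic mode
   solves a Laplace potential in the lumen instead.
4. **Cross-sections.** At points spaced every 22.2 µm of arc length, a
   plane perpendicular to the local tangent is sampled; the 0.5
   iso-contours of the interpolated lumen and lumen∪wall indicators
   give the inner and outer wall contours.  Radii follow the
   equivalent-circle formula `r = √(Area/π)`, and thickness is
   `r_out − r_in`.
5. **Statistics.** Thickness values are grouped into proximal/mid/distal
   tertiles of the main artery and of the side branches; per class we
   report n, mean, and sample SD (n−1).  Group comparisons use the
   pooled-variance unpaired two-tailed Student's t-test (Welch variant
   behind a flag); SNR = S/N and CNR = (S₁−S₂)/N with N the sample SD
   of an empty background region.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `voxel_size_um` | 7.4 | isotropic voxel pitch of the reconstruction |
| `step_um` | 22.2 | centerline sampling step (3 voxels) |
| wavelet / levels / σ | db4 / 4 / 2.0 | decomposition and damping width of the artifact filter |
| `epsilon_vox` | 0.5 | regulariser of the centerline cost |
| `GridConfig.spacing_um` | voxel/2 | in-plane sampling pitch of cross-section planes |
| `GridConfig.half_width_um` | 150 | half-extent of the cross-section plane |
| `min_n` | 100 | per-segment count below which a summary row is flagged low-n |

## Wavelet–Fourier filter

Stripes that are constant along one axis concentrate, level by level,
in one detail band of a 2D wavelet decomposition; along the stripe axis
their energy sits at Fourier index k ≈ 0.  Each band is damped with
`g(k) = 1 − exp(−k²/2σ²)` and the image reconstructed.  Small σ removes
only the strictly axis-constant component; larger σ also removes slowly
varying quasi-stripes at the cost of ghosting around compact
high-contrast structures.  Ring mode resamples the slice to polar
coordinates about the rotation centre (angular sampling: one sample per
rim voxel, i.e. `⌈2π·r_max⌉` angles; radial sampling: half a voxel;
cubic interpolation), applies the stripe filter along the angle axis,
and — importantly — maps only the **additive correction** back to
Cartesian coordinates.  The image itself never round-trips through the
polar grid, so resampling blur cannot erode thin structures such as a
two-voxel vessel wall.  Pixels outside the inscribed disk pass through
unchanged; the filter is linear and leaves a constant image exactly
unchanged.

Boundary handling uses symmetric padding.  The filter acts on
reconstructed slices, not sinograms; sinogram-domain correction is out
of scope.

## Segmentation details

Thresholds are open choices (none are prescribed by the acquisition);
with the default phantom intensities the natural choices are the
midpoints between tissue levels.  Refinement: opening then closing on
the lumen (radius configurable); **closing only** on the wall, because
opening erases a shell whose thickness is comparable to the
structuring radius; retention of one 26-connected lumen component
(largest, or the one containing a seed); 6-connected hole filling; wall
restricted to components 26-connected to the lumen shell.  Plaque
labels are never produced automatically — they enter via edit scripts
or phantom ground truth.

## Centerline details

Leaves are auto-detected as skeleton endpoints (26-connectivity) or
supplied as seeds.  Paths are traced leaf→root on the Dijkstra
predecessor tree, longest first; each later path contributes its
unclaimed suffix as a side branch.  Side branches shorter than
max(4 voxels, 1.5× the junction's inscribed radius) are discarded as
end-cap skeleton spurs.  Node positions are refined by peaking a
per-axis parabola through the local distance-transform values (offset
clamped to ±0.5 voxel) followed by a 3-point moving average with fixed
endpoints; segments are subdivided so consecutive spacing never exceeds
one voxel.  The path portion that bends into a leaf's end cap is
trimmed iteratively by the local inscribed radius (`trim_tips=False`
preserves full seed-to-seed arcs, used when comparing arc lengths
against analytic values).

Main-artery designation: the longest root-to-leaf path (depth 0).
Segment classes split each branch's own arc length at 1/3 and 2/3 —
the class names are anatomical, the boundaries are a reproducible
convention and are configurable.

## Cross-section numerics

The in-plane basis comes from Gram–Schmidt against the axis with the
smallest tangent component; areas are basis-invariant (asserted by
test).  Indicator fields are sampled trilinearly on a half-voxel plane
grid; marching squares extracts the 0.5 iso-contour enclosing the plane
origin (if several, the smallest).  Contour vertices are then refined
along radial rays from the plane origin to the 0.5 crossing of a finely
sampled cubic profile of the 3D field — marching squares alone is
biased where the indicator saturates next to the crossing.  With binary
labels the surface position is still quantised to about half a voxel;
for sub-voxel oracles the phantom can emit fractional *occupancy
fields* (`occupancy_fields`), with which equivalent radii are accurate
to ≲2 % down to 3-voxel radii.  Failure modes (origin not in lumen,
contour missing, contour clipped by the plane border) flag the row;
flagged rows are excluded from summaries but never silently dropped,
and a branch with >50 % flagged rows triggers a loud warning.

## Synthetic phantoms

Branches are swept circles along polylines with linearly interpolated
inner radius and wall thickness; plaques add a boxcar of extra
thickness over an arc interval, labelled separately.  Truth labels use
a crisp voxel-centre test with flat tube end caps (so cylinder-volume
oracles hold); the grayscale rendering optionally supersamples
partial-volume edges (3³ sub-voxel average near surfaces).  The organ
envelope is an ellipsoid: parenchyma inside, background outside.

Default intensity levels reproduce the study's tissue SNRs at unit
background noise (wall 139.7, parenchyma 134.2, lumen 120.1, arbitrary
units).  The background level defaults to 110 — the specimen is
embedded in agarose gel, whose refractive-index decrement in phase
contrast is close to soft tissue, *not* to vacuum.  This matters for
ring removal: an implausibly dark background would make the specimen
boundary a near-circular edge of enormous contrast whose angularly
coherent component is indistinguishable from a ring artifact.

Corruption adds i.i.d. Gaussian noise, column-constant stripe offsets
and concentric Gaussian ring offsets (identical per slice), all
deterministic for a given seed.  For recovery studies the artifact
amplitudes are 5× the noise SD — clearly visible against tissue
contrasts of ~5–20× noise — the rings deliberately cross the vessel's
radial band, and the envelope is elongated along the slice axis so its
edge radii stay disjoint from the vessel's radial band in every slice
(as in a real scan, where the heart surface does not graze the
coronary arteries).

What the phantoms do **not** emulate: tomographic reconstruction
physics (beam hardening, phase wrapping, streaks), anisotropic
resolution, intensity inhomogeneity, motion, collapsed or touching
vessels, and plaque substructure.  Passing recovery tests therefore
demonstrates correctness of the measurement chain, not robustness to
every real-data pathology.

## Problem sizes

Recovery studies run on 96×160×160 phantoms (inner radius 30 µm, wall
15–37 µm, ≈1 mm₊ of vessel), chosen so the vessel subtends a small
angle from the rotation centre — the regime in which ring filtering is
physically meaningful — while single runs complete in seconds.  The
sampling-density computation uses a 2.3 mm tube in a 330×44×44 volume.

## Known limitations

- Thickness from binary label maps carries a ±half-voxel surface
  quantisation; at 7.4 µm voxels the thinnest distal walls (13–15 µm)
  are only ~2 voxels, so per-point values there are dominated by
  discretisation (means over ≥100 points remain accurate).
- The wavelet–Fourier filter removes any angularly coherent component
  at a given radius; genuinely ring-like anatomy would be attenuated.
- Tertile segment boundaries are a convention, not anatomy.
- The minimal-path centerline can shortcut on strongly non-convex
  lumina; the harmonic mode is more faithful but solves a sparse
  Laplace system per component and is practical only for small masks.
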