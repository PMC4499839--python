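import numpy as np
import pytest

from vesselmorph.phantom import BranchSpec, PhantomSpec, generate_phantom

VOX = 7.4  # um, the acquisition's isotropic voxel size


def make_tube_spec(shape=(120, 64, 64), r_in=50.0, wall=30.0,
                   center_vox=(32.5, 32.5), lo_vox=12, hi_vox=108,
                   voxel=VOX, **kw):
    """Straight axial tube with the axis through voxel centres."""
    cy = center_vox[0] * voxel
    cx = center_vox[1] * voxel
    pts = np.array([[lo_vox * voxel, cy, cx], [hi_vox * voxel, cy, cx]])
    return PhantomSpec(shape=shape,
                       branches=[BranchSpec(pts, r_in, wall)],
                       voxel_size_um=voxel, **kw)


@pytest.fixture(scope="session")
def tube_spec():
    return make_tube_spec()


@pytest.fixture(scope="session")
def tube_bundle(tube_spec):
    return generate_phantom(tube_spec)


@pytest.fixture(scope="session")
def tube_axis_um(tube_spec):
    return tube_spec.branches[0].points_um.copy()


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
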