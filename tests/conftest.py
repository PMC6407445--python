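import numpy as np
import pytest

from snsvta import anatomy, axon, field, geometry
from snsvta.labels import CONTACT0, FAT, IPG


@pytest.fixture(scope="session")
def morph_short():
    """40 mm fibre (81 nodes): fast stand-in for axon-level tests."""
    return axon.build_axon(5.7, 40.0)


@pytest.fixture(scope="session")
def morph_full():
    return axon.build_axon(5.7, 100.0)


def point_source_unit_potentials(morph, distance_mm, x0_mm=None):
    """Analytic extracellular profile of a point source ``distance_mm`` from the
    fibre, normalised to -1 V at the closest compartment (homogeneous medium)."""
    x = morph.x_center_um * 1e-3
    if x0_mm is None:
        x0_mm = x.mean()
    r = np.sqrt((x - x0_mm) ** 2 + distance_mm ** 2)
    return -distance_mm / r


@pytest.fixture(scope="session")
def small_homogeneous():
    """Homogeneous fat box large enough for a lead and 30 mm fibres.

    Extents are exact voxel multiples (70 x 35 x 35 voxels) so the lead can
    sit on the symmetry axis of the grid."""
    p = anatomy.PelvisParams(extent_mm=(80.5, 40.25, 40.25), voxel_mm=1.15)
    return anatomy.make_homogeneous(p)


@pytest.fixture(scope="session")
def centered_placement():
    # y = z = 20.125 mm is the centre-voxel line of the 35-voxel transverse grid
    return geometry.Placement((20.0, 20.125, 20.125), (1.0, 0.0, 0.0))


def concentric_spheres_tissue(n=73, voxel=0.5, a=3.0, b=18.0):
    """Uniform medium with a spherical cathode (radius ``a``) at the centre and a
    grounded shell at radius ``b``; the analytic solution between them is
    V(r) = -(1/r - 1/b) / (1/a - 1/b)."""
    shape = (n, n, n)
    labels = np.full(shape, FAT, dtype=np.int16)
    c = n * voxel / 2.0
    coords = (np.arange(n) + 0.5) * voxel - c
    xx, yy, zz = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
    labels[r <= a] = CONTACT0
    labels[r >= b] = IPG
    table = {FAT: 0.01, CONTACT0: 0.0, IPG: 0.0}
    tissue = anatomy.TissueModel(labels, (voxel,) * 3, (0.0, 0.0, 0.0), table)
    return tissue, r


@pytest.fixture(scope="session")
def spheres_solution():
    tissue, r = concentric_spheres_tissue()
    stim = field.StimConfig("monopolar", 0, "ipg", 1.0)
    return field.solve_potential(tissue, stim), r
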