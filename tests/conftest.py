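"""Shared fixtures: small hand-built volumes and generated phantoms."""

import numpy as np
import pytest

import tomolink as tl


@pytest.fixture(scope="session")
def voxel():
    return 3.2  # nm, the standard binned pixel size


@pytest.fixture(scope="session")
def bridge_phantom(voxel):
    """Two 20-nm-radius vesicles 60 nm apart (20 nm gap) joined by a dense
    cylindrical bridge, built directly from the rendering primitives."""
    shape = (48, 48, 48)
    data = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    c1 = np.array([76.8, 76.8, 46.8])
    c2 = np.array([76.8, 76.8, 106.8])  # 60 nm apart along x
    m1 = tl.render_sphere_shell(c1, 0.0, 20.0, -2.0, data, voxel)
    m2 = tl.render_sphere_shell(c2, 0.0, 20.0, -2.0, data, voxel)
    labels[m1] = 1
    labels[m2] = 2
    # dense bridge spanning the 20-nm gap (overshoot into both balls; the
    # labeled voxels are not overwritten)
    from tomolink.synthetic import _render_linker
    _render_linker(c1 + [0, 0, 20.0], c2 - [0, 0, 20.0], 2.4, -1.5,
                   data, voxel, labels == 0, overshoot_nm=1.5 * voxel)
    catalog = {1: tl.Boundary(1, "vesicle", c1, 20.0, "sv"),
               2: tl.Boundary(2, "vesicle", c2, 20.0, "sv")}
    density = tl.DensityVolume(data, voxel)
    labelvol = tl.LabelVolume(labels, catalog, voxel)
    return density, labelvol, (c1, c2)


@pytest.fixture(scope="session")
def pair_phantom():
    """Generated phantom: 12 vesicles as 6 connector pairs plus a plasma
    membrane with 3 tethered vesicles; noise-free."""
    spec = tl.PhantomSpec(
        volume_shape=(96, 96, 96), voxel_size_nm=3.2, rng_seed=42,
        vesicles=[tl.VesicleSpec(kind="sv", diameter_nm=40, count=15)],
        plasma_membrane=tl.MembraneSpec(),
        connectors=tl.LinkerSpec(fraction_of_vesicles_connected=0.8,
                                 topology="pairs"),
        tethers=tl.LinkerSpec(fraction_of_vesicles_connected=0.2,
                              length_mean_nm=19.8, length_sd_nm=11.7),
    )
    return spec, *tl.generate_phantom(spec)


@pytest.fixture(scope="session")
def noise_free_schedule():
    return tl.ThresholdSchedule(np.linspace(-1.9, -0.2, 25))
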