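import numpy as np
import pytest

from spheroidquant import phantom


@pytest.fixture(scope="session")
def spheroid_phantom():
    """Default lumen-bearing spheroid with 3 planted delaminated cells."""
    spec = phantom.PhantomSpec(seed=1)
    img, labels, truth = phantom.make_spheroid_phantom(spec)
    return spec, img, labels, truth


@pytest.fixture(scope="session")
def micro_phantom():
    """Microcavity structure with a planted 2:1 tip:side density ratio."""
    spec = phantom.PhantomSpec(geometry="microcavity", seed=3)
    img, labels, truth = phantom.make_microcavity_phantom(spec)
    return spec, img, labels, truth


@pytest.fixture(scope="session")
def plane_phantom():
    """Embryo plane with anterior/posterior ROIs and a planted GFP subset."""
    spec = phantom.PhantomSpec(geometry="plane2d", seed=5)
    img, labels, truth = phantom.make_embryo_plane_phantom(spec)
    return spec, img, labels, truth


def nucleus_centroids_um(labels, voxel_size):
    """Per-nucleus centroids in physical um from the label mask."""
    vs = np.asarray(voxel_size, float)
    out = {}
    for i in np.unique(labels.nuclei[labels.nuclei > 0]):
        out[int(i)] = np.argwhere(labels.nuclei == i).mean(axis=0) * vs
    return out
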