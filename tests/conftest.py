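import numpy as np
import pytest

from bctdensity.features import compose_features
from bctdensity.phantom import PhantomSpec, generate_phantom
from bctdensity.quadrants import assign_quadrants, locate_nipple
from bctdensity.segmentation import segment_all
from bctdensity.volume import CTVolume, LabelMap, Tissue

# Medium noiseless phantom: large enough for realistic morphology, small
# enough to segment in a few seconds; shared session-wide.
MEDIUM_KWARGS = dict(
    grid_shape=(128, 120, 120),
    breast_semiaxes=(30.0, 16.0, 16.0),
    n_gland_components=6,
    gland_volume_target=2.4,
    pectoral_slab_depth=12,
    noise_sd=0.0,
    seed=1,
)

# Tiny phantom for cheap per-test generation (I/O, CLI, pipeline tests).
TINY_KWARGS = dict(
    grid_shape=(80, 72, 72),
    breast_semiaxes=(17.0, 9.5, 9.5),
    n_gland_components=2,
    gland_volume_target=0.25,
    pectoral_slab_depth=8,
    include_ribs=False,
    include_skinfold=False,
    nipple_radius=2.5,
    noise_sd=0.0,
    seed=0,
)


def tiny_spec(**overrides) -> PhantomSpec:
    return PhantomSpec(**{**TINY_KWARGS, **overrides})


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0


@pytest.fixture(scope="session")
def medium_phantom():
    spec = PhantomSpec(**MEDIUM_KWARGS)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def medium_segmentation(medium_phantom):
    _, volume, _ = medium_phantom
    return segment_all(volume)


@pytest.fixture(scope="session")
def medium_composition(medium_phantom, medium_segmentation):
    _, volume, _ = medium_phantom
    labels = medium_segmentation.label_map
    nipple = locate_nipple(labels)
    partition = assign_quadrants(labels, nipple)
    return partition, compose_features(volume, labels, partition)


@pytest.fixture
def synthetic_labelmap():
    """Hand-built 10x10x10 label map: 1000-voxel block of known classes."""
    labels = np.zeros((10, 10, 10), dtype=np.uint8)
    labels[2:8] = Tissue.ADIPOSE
    labels[4:6, 4:6, 4:6] = Tissue.GLAND
    labels[8] = Tissue.SKIN
    return LabelMap(labels=labels, voxel_size=0.3)


def flat_volume(shape, value, voxel_size=0.3) -> CTVolume:
    return CTVolume(hu=np.full(shape, value, dtype=np.float32), voxel_size=voxel_size)
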