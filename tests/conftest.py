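import numpy as np
import pytest

from flairvol.phantom import CLASSES, default_spec, generate_phantom
from flairvol.preprocessing import VolumeImage

SMALL_GRID = (24, 24, 16)


@pytest.fixture(scope="session")
def small_phantoms():
    """One small phantom per class, generated once per session."""
    out = {}
    for label in CLASSES:
        spec = default_spec(label, seed=11, grid_shape=SMALL_GRID)
        out[label] = generate_phantom(spec, subject_id=f"{label}000")
    return out


@pytest.fixture(scope="session")
def tiny_cohort_arrays():
    """Eight tiny labeled volumes (two per class) as (x, y) arrays."""
    vols, labels = [], []
    for ci, label in enumerate(CLASSES):
        for i in range(2):
            spec = default_spec(label, seed=100 + ci * 10 + i, grid_shape=SMALL_GRID)
            vols.append(generate_phantom(spec).data)
            labels.append(ci)
    return np.stack(vols), np.asarray(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_volume(rng):
    """A sparse random nonnegative volume wrapped as a VolumeImage."""
    data = np.zeros((20, 18, 7), dtype=np.float32)
    mask = rng.random(data.shape) < 0.05
    data[mask] = rng.random(mask.sum()).astype(np.float32) + 0.1
    if not mask.any():
        data[5, 5, 3] = 1.0
    return VolumeImage(data)
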