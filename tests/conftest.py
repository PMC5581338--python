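import numpy as np
import pytest

from nodulecad.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small but complete phantom: 4 nodules per class, 4 raters each."""
    spec = PhantomSpec(
        volume_shape=(40, 96, 96), n_nodules_per_class=4, seed=42
    )
    volume, annotations = generate_phantom(spec)
    return spec, volume, annotations


@pytest.fixture(scope="session")
def separable_patches():
    """30 trivially separable patches (10 per class) at three intensity
    levels, mimicking normalized ground-glass / mixed / solid ROIs."""
    rng = np.random.default_rng(1)
    images, labels = [], []
    for c, level in enumerate((0.25, 0.5, 0.75)):
        for _ in range(10):
            img = np.clip(level + rng.normal(0, 0.02, (64, 64)), 0, 1)
            images.append(img)
            labels.append(c)
    return np.asarray(images), np.asarray(labels)
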