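import numpy as np
import pytest

from scalestack.records import ImageRecord
from scalestack.synth import DatasetSpec, FindingSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_texture_dataset():
    """200 images at 64px with one pure texture finding (affinity 64)."""
    spec = DatasetSpec(
        n_images=200,
        findings=[FindingSpec("tex", 0.5, 64, amplitude=(10.0, 22.0))],
        resolution=64,
        seed=11,
    )
    records = generate_dataset(spec)
    labels = np.stack([r.labels for r in records])
    return spec, records, labels


@pytest.fixture()
def flat_image():
    return ImageRecord("flat", np.full((64, 64), 128, dtype=np.uint8))
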