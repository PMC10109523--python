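import numpy as np
import pytest

from tumorkit import phantoms
from tumorkit.image_io import GrayImage2D, LabeledRecord


@pytest.fixture(scope="session")
def tumor_phantom():
    return phantoms.make_phantom2d(phantoms.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def healthy_phantom():
    return phantoms.make_phantom2d(phantoms.PhantomSpec(with_tumor=False, seed=12))


@pytest.fixture(scope="session")
def detection_records():
    """60 balanced phantom records (30 tumor / 30 healthy)."""
    records = []
    for i in range(60):
        with_tumor = i < 30
        img, _, label = phantoms.make_phantom2d(
            phantoms.PhantomSpec(with_tumor=with_tumor, seed=500 + i))
        name = f"{'Y' if label else 'N'}{i}.png"
        records.append(LabeledRecord(image=img, mask=None, label=label, name=name))
    return records


def gray(arr, value_range="byte"):
    return GrayImage2D(np.asarray(arr, dtype=float), value_range=value_range)
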