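import numpy as np
import pytest

from satdrive import (
    ArraySpec,
    GuideSpec,
    SatelliteArray,
    UnitAnnotation,
    UnitClass,
    gen_array,
)


@pytest.fixture(scope="session")
def default_array():
    """A seeded synthetic satellite array with its ground truth."""
    return gen_array(ArraySpec(seed=11))


@pytest.fixture
def tiny_array():
    """Hand-built 12-unit array: 5 L + 5 R dimers, 1 variant, 1 truncated, 2 TE islands."""
    units = []
    pos = 0
    layout = (
        [(UnitClass.REPEAT_LEFT, 120), (UnitClass.REPEAT_RIGHT, 120)] * 5
        + [(UnitClass.TE_ISLAND, 500), (UnitClass.REPEAT_VARIANT, 120),
           (UnitClass.REPEAT_TRUNCATED, 60), (UnitClass.TE_ISLAND, 300)]
    )
    for cls, length in layout:
        units.append(
            UnitAnnotation(
                contig="ctg", start=pos, end=pos + length, strand="+", unit_class=cls
            )
        )
        pos += length
    return SatelliteArray(contig="ctg", units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
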