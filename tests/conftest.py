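import numpy as np
import pytest

from dpcrmux.codebook import Codebook, TagSignature, enumerate_codebook


@pytest.fixture(scope="session")
def cb32() -> Codebook:
    """Full 32-tag codebook: 4 channels, 2 levels, up to 2 probe sites."""
    return enumerate_codebook(4, 2, 2)


@pytest.fixture(scope="session")
def cb3() -> Codebook:
    """The worked three-tag example codebook {1000, 0100, 1100}."""
    return Codebook(
        4,
        2,
        2,
        (
            TagSignature.from_string("1000"),
            TagSignature.from_string("0100"),
            TagSignature.from_string("1100"),
        ),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_codebook(
    gen: np.random.Generator, max_channels: int = 4, max_tags: int = 32
) -> Codebook:
    """A random sub-codebook for property tests (C <= 4, <= 32 tags)."""
    channels = int(gen.integers(1, max_channels + 1))
    full = enumerate_codebook(channels, 2, channels)
    n = int(gen.integers(1, min(max_tags, len(full)) + 1))
    idx = gen.choice(len(full), size=n, replace=False)
    tags = tuple(full.tags[i] for i in sorted(idx))
    return Codebook(channels, 2, channels, tags)
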