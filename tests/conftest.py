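import numpy as np
import pytest

from wepa import AnchorSet, EmbeddingSpace


@pytest.fixture
def tiny_space() -> EmbeddingSpace:
    """Four tokens in 2-D with hand-friendly geometry."""
    return EmbeddingSpace(
        tokens=["run", "gym", "quit", "rest"],
        vectors=np.array([[1.0, 0.0], [0.8, 0.2], [-1.0, 0.0], [-0.7, -0.3]]),
        source_tag="tiny",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_space(rng) -> EmbeddingSpace:
    n, d = 40, 6
    return EmbeddingSpace(
        tokens=[f"tok{i:02d}" for i in range(n)],
        vectors=rng.normal(size=(n, d)),
        source_tag="random",
    )


@pytest.fixture
def bipolar_anchors() -> tuple[AnchorSet, AnchorSet]:
    pos = AnchorSet("commit", "pos", ("run", "gym"))
    neg = AnchorSet("commit", "neg", ("quit", "rest"))
    return pos, neg
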