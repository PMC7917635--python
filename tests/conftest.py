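import numpy as np
import pytest
from hypothesis import settings

from posturekit.types import LABEL_ORDER, PostureLabel, PostureTimeline

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_timeline(rng: np.random.Generator, length: int | None = None,
                    with_unknown: bool = False) -> PostureTimeline:
    """A random label-per-second timeline with run structure."""
    length = length if length is not None else int(rng.integers(1, 200))
    labels = []
    pool = list(LABEL_ORDER) + ([PostureLabel.UNKNOWN] if with_unknown else [])
    while len(labels) < length:
        lab = pool[rng.integers(len(pool))]
        run = int(rng.integers(1, 30))
        labels.extend([lab] * run)
    return PostureTimeline(
        worker_id="w", trade="t",
        start_epoch=int(rng.integers(0, 10_000)) * 1000,
        labels=labels[:length],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
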