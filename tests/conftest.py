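import numpy as np
import pytest

from phonogroup import SimSpec, generate_corpus
from phonogroup.gmm import MapConfig


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny feature-mode corpus with a strong plosive effect (session-wide
    read-only fixture)."""
    spec = SimSpec(
        n_speakers_per_class=4,
        utterances_per_speaker=2,
        class_effect={"plosive": (1.5, 1.0)},
        seed=42,
        corpus_id="fix",
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_store(small_corpus):
    return small_corpus.to_store()


@pytest.fixture()
def map_config():
    return MapConfig(init_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
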