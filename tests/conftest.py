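import numpy as np
import pytest

from protcleave.dataset import build_samples
from protcleave.encoders import EncodingContext, build_knn_reference
from protcleave.io import load_blosum62
from protcleave.synthetic import caspase_like_motif, generate_substrates


@pytest.fixture(scope="session")
def blosum():
    return load_blosum62()


@pytest.fixture(scope="session")
def small_substrates():
    """20 substrates with strong planted caspase-like sites."""
    subs, tracks = generate_substrates(
        20,
        caspase_like_motif(0.9),
        length_range=(60, 100),
        sites_per_substrate=2,
        seed=42,
        with_tracks=True,
    )
    return subs, tracks


@pytest.fixture(scope="session")
def small_samples(small_substrates):
    subs, _ = small_substrates
    return build_samples(subs, "X01.001", ratio_neg_per_pos=3, seed=7)


@pytest.fixture(scope="session")
def knn_context(small_samples):
    ref = build_knn_reference(small_samples.windows)
    return EncodingContext(schemes=("BINARY", "AAC", "KNN"), knn_ref=ref)
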