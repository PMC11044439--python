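import numpy as np
import pytest

from cwgcna.datamodel import OmicsMatrix


@pytest.fixture
def small_matrix() -> OmicsMatrix:
    """3 features x 4 samples with distinct, non-degenerate values."""
    rng = np.random.default_rng(0)
    return OmicsMatrix(
        rng.normal(size=(3, 4)), ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], "RNA"
    )


@pytest.fixture
def random_matrix():
    def make(n_features=30, n_samples=20, seed=0, omic_label="RNA") -> OmicsMatrix:
        rng = np.random.default_rng(seed)
        return OmicsMatrix(
            rng.normal(size=(n_features, n_samples)),
            [f"g{i}" for i in range(n_features)],
            [f"s{i}" for i in range(n_samples)],
            omic_label,
        )

    return make
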