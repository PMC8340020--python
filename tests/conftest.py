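"""Shared fixtures: small synthetic inputs and one reusable trained model."""

import numpy as np
import pytest

from cdr3vec.airr_io import TrimConfig, trim_cdr3
from cdr3vec.embedding import CDR3Embedder
from cdr3vec.synthetic import SyntheticConfig, generate_repertoires


@pytest.fixture(scope="session")
def small_records():
    """A small but realistic synthetic repertoire set (4 subjects x 300)."""
    cfg = SyntheticConfig(
        n_subjects_per_cohort=2, n_sequences_per_subject=300, seed=42
    )
    records, manifest = generate_repertoires(cfg)
    return records, manifest


@pytest.fixture(scope="session")
def toy_model():
    """A model trained on a tiny deterministic corpus covering a known vocabulary."""
    rng = np.random.default_rng(0)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    grams = ["".join(rng.choice(list(alphabet), 3)) for _ in range(60)]
    sentences = [
        [grams[rng.integers(60)] for _ in range(4)] for _ in range(400)
    ]
    return CDR3Embedder(dim=16, epochs=3, seed=0).fit(sentences)


@pytest.fixture(scope="session")
def trimmed_small(small_records):
    records, _ = small_records
    trim = TrimConfig()
    return records, [trim_cdr3(r.cdr3_aa, trim) for r in records]
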