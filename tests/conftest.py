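import numpy as np
import pytest

from ppistack.io import ProteinRecord
from ppistack.synthetic import SyntheticConfig, attach_mock_pssms, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """50 synthetic labeled sequences with mock PSSMs attached."""
    cfg = SyntheticConfig(n_sequences=50, length_range=(40, 80), seed=11)
    records = generate_dataset(cfg)
    attach_mock_pssms(records, cfg)
    return cfg, records


@pytest.fixture
def tiny_record():
    rng = np.random.default_rng(5)
    seq = "ACDEFGHIKLMNPQRSTVWYACDEF"
    labels = rng.integers(0, 2, len(seq))
    return ProteinRecord("tiny", seq, labels, pssm=rng.normal(size=(len(seq), 20)))
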