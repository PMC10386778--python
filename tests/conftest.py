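import warnings

import pytest

from stacktide.synthetic import SyntheticConfig, generate

warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn.neural_network")


@pytest.fixture(scope="session")
def strong_ds():
    """120-peptide strong-signal dataset shared by pipeline-level tests."""
    return generate(SyntheticConfig(n_pos=60, n_neg=60, effect="strong", seed=11))


@pytest.fixture(scope="session")
def null_ds():
    """Signal-free dataset: both classes drawn from one distribution."""
    return generate(SyntheticConfig(n_pos=60, n_neg=60, effect="none", seed=12))
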