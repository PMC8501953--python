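import numpy as np
import pytest

from dropgate import AssayModel, CellClass

TPR = 0.971
FPR = 2e-4


@pytest.fixture
def positive_class():
    return CellClass("positive", {"FAM": TPR}, stain_level=1000.0)


@pytest.fixture
def negative_class():
    return CellClass("negative", {"FAM": FPR}, stain_level=1000.0)


@pytest.fixture
def pure_positive_model(positive_class):
    return AssayModel(classes=[positive_class], proportions=[1.0], seed=11)


@pytest.fixture
def mixture_model(positive_class, negative_class):
    """10% positive cells in a negative background."""
    return AssayModel(
        classes=[positive_class, negative_class],
        proportions=[0.1, 0.9],
        seed=12,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
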