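"""Shared fixtures: deterministic random sequences and the two end-to-end
simulation experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from chondriome.experiments import false_positive_control, hsnp_recovery
from chondriome.thresholds import AnalysisThresholds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def thresholds() -> AnalysisThresholds:
    return AnalysisThresholds()


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def recovery_metrics():
    """Two-mitotype 0.8/0.2 recovery experiment at 100x, 1% error, 50 kb."""
    return hsnp_recovery(seed=1)


@pytest.fixture(scope="session")
def fp_control():
    """Homoplasmic false-positive stress control (20x, 5% error, 50 kb)."""
    return false_positive_control(seed=1)
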