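import numpy as np
import pytest

from tensorqr import TuckerFactorization


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_factorization(rng, dims, rank) -> TuckerFactorization:
    return TuckerFactorization(
        rng.standard_normal(tuple(rank)),
        [rng.standard_normal((p, r)) for p, r in zip(dims, rank)],
    )


def assert_monotone_within_nu(loss_path, context=""):
    """Objective must never increase across block updates at fixed nu."""
    for prev, cur in zip(loss_path, loss_path[1:]):
        if cur[0] == prev[0]:  # same nu stage
            assert cur[3] <= prev[3], (
                f"objective increased within a nu stage {context}: "
                f"{prev} -> {cur}"
            )
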