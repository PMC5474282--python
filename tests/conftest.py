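import numpy as np
import pytest

from cdglda import synthetic
from cdglda.corpus import BillingRecord


@pytest.fixture()
def tiny_records():
    """Two traces, three days, with an in-day duplicate to exercise merging."""
    return [
        BillingRecord("T1", "A", 3, 1),
        BillingRecord("T1", "A", 1, 1),
        BillingRecord("T1", "B", 2, 1),
        BillingRecord("T1", "A", 1, 2),
        BillingRecord("T2", "C", 4, 1),
    ]


@pytest.fixture(scope="session")
def small_synth():
    """A small planted-topic corpus shared across read-only tests."""
    return synthetic.generate(
        synthetic.GeneratorConfig(n_traces=10, days_range=(4, 8), seed=123)
    )


@pytest.fixture(scope="session")
def staged_synth():
    """Staged corpus walking an absorbing admission→treatment→re-exam chain."""
    cfg = synthetic.GeneratorConfig(
        n_traces=40, days_range=(6, 12), seed=7,
        stages=synthetic.default_stage_config(3),
    )
    return synthetic.staged_traces(cfg)


def best_permutation_tv(phi: np.ndarray, phi_star: np.ndarray) -> float:
    """Mean total-variation distance under the best topic permutation."""
    from itertools import permutations

    return min(
        0.5 * np.abs(phi[list(p)] - phi_star).sum(axis=1).mean()
        for p in permutations(range(phi.shape[0]))
    )
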