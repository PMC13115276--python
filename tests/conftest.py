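import numpy as np
import pytest

from sdd_dpsgd import (
    ScheduleConfig,
    generate_gaussian_mixture,
    ham10000_like_preset,
    train_val_split,
)


@pytest.fixture(scope="session")
def sdd_schedule():
    """Dual dynamic schedule at the method's experimental parameters."""
    return ScheduleConfig(
        total_iterations=2000, sigma0=1.0, c0=5.0,
        gamma=0.9, beta=0.8, clip_decay=0.6, rho=0.3, n=3,
    )


@pytest.fixture(scope="session")
def small_imbalanced_split():
    """Small 7-class imbalanced dataset with an 80/20 stratified split."""
    ds = generate_gaussian_mixture(ham10000_like_preset(n_samples=1200, seed=0))
    return train_val_split(ds, fraction=0.8, seed=0)
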