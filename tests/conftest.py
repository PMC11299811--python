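import numpy as np
import pandas as pd
import pytest

from ldcconf import DDMParams, LDCParams, balanced_design, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def baseline_ddm():
    return DDMParams(drift_rates=(0.3, 0.2, 0.1), bound=0.1, non_decision_time=0.3)


@pytest.fixture(scope="session")
def baseline_ldc():
    return LDCParams(alpha=18.0, beta=0.0)


@pytest.fixture(scope="session")
def baseline_table(baseline_ddm, baseline_ldc):
    """One participant, 3 difficulties x 216 trials, baseline readout."""
    rng = np.random.default_rng(777)
    return simulate_dataset(baseline_ddm, baseline_ldc, balanced_design(216), rng=rng)


@pytest.fixture(scope="session")
def big_baseline_table(baseline_ddm, baseline_ldc):
    """~10k-trial baseline simulation for distributional checks."""
    rng = np.random.default_rng(1234)
    return simulate_dataset(
        baseline_ddm, baseline_ldc, balanced_design(3400), rng=rng
    )


@pytest.fixture(scope="session")
def three_condition_table(baseline_ddm):
    """Trials across the minus/baseline/plus conditions with beta varying."""
    rng = np.random.default_rng(99)
    ldc = {
        "minus": LDCParams(alpha=18.0, beta=-1.0),
        "baseline": LDCParams(alpha=18.0, beta=0.0),
        "plus": LDCParams(alpha=18.0, beta=1.0),
    }
    design = balanced_design(72, 3, conditions=("minus", "baseline", "plus"))
    return simulate_dataset(baseline_ddm, ldc, design, rng=rng)
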