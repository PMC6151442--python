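import numpy as np
import pandas as pd
import pytest

from qpar import (
    CassetteAssignment,
    FeatureTable,
    GeneratorConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_truth():
    """Compact synthetic dataset (66 blends × 20 features, 3 actives)."""
    return generate_dataset(GeneratorConfig(n_features=20, n_cassettes=3, seed=11))


@pytest.fixture
def tiny_table():
    """4 samples × 3 features with simple integer abundances."""
    ab = pd.DataFrame(
        {"a": [2.0, 4.0, 6.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0], "c": [0.0, 1.0, 2.0, 3.0]},
        index=["s1", "s2", "s3", "s4"],
    )
    rts = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    return FeatureTable(abundance=ab, retention_times=rts)


@pytest.fixture
def one_cassette():
    return CassetteAssignment.single(["a", "b", "c"])


def olmstead_brute(conc, potencies, powers, labels):
    """Independent scalar-loop oracle for the Olmstead predictor."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    out = []
    for row in conc:
        surv = 1.0
        for g in sorted(set(labels)):
            s = sum(c / e for c, e, lab in zip(row, potencies, labels) if lab == g)
            p = powers[g - 1]
            e_g = s**p / (1.0 + s**p) if np.isfinite(s**p) else 1.0
            surv *= 1.0 - e_g
        out.append(1.0 - surv)
    return np.array(out)
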