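import numpy as np
import pandas as pd
import pytest

from lncq import normalization


@pytest.fixture
def small_ct():
    """3 targets + 2 housekeeping genes x 4 samples, noise-free."""
    samples = [f"S{i}" for i in range(1, 5)]
    ct = pd.DataFrame(
        {
            s: [25.0 + i, 24.0, 26.0, 20.0, 22.0]
            for i, s in enumerate(samples)
        },
        index=["T1", "T2", "T3", "HK1", "HK2"],
    )
    roles = {"T1": "target", "T2": "target", "T3": "target",
             "HK1": "housekeeping", "HK2": "housekeeping"}
    return normalization.CtMatrix(ct=ct, feature_roles=roles)


@pytest.fixture
def two_group_expr():
    """Factory: log2 expression with a planted group difference on feature F1."""

    def make(n_per_group=20, n_features=6, effect=1.0, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"A{i}" for i in range(n_per_group)] + [
            f"B{i}" for i in range(n_per_group)
        ]
        meta = pd.DataFrame(
            {
                "group": ["a"] * n_per_group + ["b"] * n_per_group,
                "sex": list(np.where(np.arange(2 * n_per_group) % 2, "male", "female")),
            },
            index=samples,
        )
        X = rng.normal(0, noise, size=(n_features, 2 * n_per_group))
        X[0, :n_per_group] += effect
        expr = pd.DataFrame(
            X, index=[f"F{i + 1}" for i in range(n_features)], columns=samples
        )
        return expr, meta

    return make
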