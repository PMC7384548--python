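import numpy as np
import pandas as pd
import pytest

from maic import AggregateTarget, CovariateTarget, IPDTable


def make_ipd(covariates: dict, arm=None, outcome=None, base_weight=None) -> IPDTable:
    """Build a validated IPDTable from plain arrays."""
    names = list(covariates)
    n = len(next(iter(covariates.values())))
    if arm is None:
        arm = np.where(np.arange(n) % 2 == 0, "A", "B")
    df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "arm": arm})
    for name in names:
        df[name] = np.asarray(covariates[name], dtype=float)
    if outcome is not None:
        df["outcome"] = np.asarray(outcome, dtype=float)
    if base_weight is not None:
        df["base_weight"] = np.asarray(base_weight, dtype=float)
    return IPDTable.from_frame(df, names)


def make_target(means: dict, binary=(), variances=None, **kwargs) -> AggregateTarget:
    targets = [
        CovariateTarget(
            name,
            mean,
            variance=(variances or {}).get(name),
            binary=name in binary,
        )
        for name, mean in means.items()
    ]
    return AggregateTarget(covariate_targets=targets, **kwargs)


@pytest.fixture
def micro_ipd() -> IPDTable:
    """Two subjects with binary covariate (0, 1): the closed-form instance."""
    return make_ipd({"x": [0.0, 1.0]}, arm=["A", "B"], outcome=[0.0, 10.0])


@pytest.fixture
def micro_target() -> AggregateTarget:
    return make_target({"x": 0.7}, binary=("x",))


def qp_feasible_weights(Z: np.ndarray) -> np.ndarray:
    """Independent oracle: the equality-constrained least-squares weights.

    Minimizes Σ(w_i − 1/N)² subject to Σw = 1 and Zᵀw = 0 — the Euclidean
    projection of uniform weights onto the balance constraints, via the
    normal equations of the constraint system.
    """
    n = Z.shape[0]
    A = np.column_stack([np.ones(n), Z])
    b = np.zeros(A.shape[1])
    b[0] = 1.0
    nu = np.linalg.solve(A.T @ A, b - A.T @ np.full(n, 1.0 / n))
    return 1.0 / n + A @ nu
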