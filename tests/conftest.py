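import numpy as np
import pandas as pd
import pytest

from scsurv.containers import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 cells raw matrix with simple integer counts."""
    values = pd.DataFrame(
        [[1.0, 0.0, 2.0, 3.0],
         [2.0, 3.0, 0.0, 1.0],
         [0.0, 0.0, 4.0, 0.0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return ExpressionMatrix(values=values, stage="raw")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def brute_force_cindex(t, delta, r) -> float:
    """Independent pair-enumeration oracle for the concordance index.

    Counts ordered pairs (i, j) with t_i < t_j and an observed event for i;
    concordant when r_i > r_j, half credit for tied risk scores.
    """
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if t[i] < t[j] and delta[i] == 1:
                den += 1
                if r[i] > r[j]:
                    num += 1
                elif r[i] == r[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def newton_raphson_cox(x, time, event, tol=1e-12, max_iter=200) -> float:
    """Single-covariate unpenalized Cox MLE by Newton-Raphson (no ties).

    Maximizes the partial likelihood l(b) = sum over events of
    [b*x_i - log(sum of exp(b*x_j) over the risk set at t_i)].
    """
    x = np.asarray(x, dtype=float)
    b = 0.0
    for _ in range(max_iter):
        grad = hess = 0.0
        for i in range(len(time)):
            if event[i] != 1:
                continue
            risk = time >= time[i]
            w = np.exp(b * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            grad += x[i] - s1 / s0
            hess += -(s2 / s0 - (s1 / s0) ** 2)
        step = grad / hess
        b -= step
        if abs(step) < tol:
            break
    return b
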