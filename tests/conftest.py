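import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def small_meta():
    """Longitudinal scan metadata for GAM tests: 30 participants, 1-3 scans
    each, ages spanning 0-287 days."""
    rng = np.random.default_rng(0)
    rows = []
    for p in range(30):
        sex = rng.choice(["F", "M"])
        for _ in range(rng.integers(1, 4)):
            rows.append(dict(
                participant_id=f"P{p:02d}",
                corrected_age=rng.uniform(0, 287),
                sex=sex,
                scanner=rng.choice(["A", "B"]),
                mean_fd=rng.gamma(2, 0.05),
            ))
    return pd.DataFrame(rows)


def naive_u_centered(x):
    """Explicit four-term double-loop U-centering (oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    a = np.abs(np.subtract.outer(x, x))
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                A[i, j] = (
                    a[i, j]
                    - a[i, :].sum() / (n - 2)
                    - a[:, j].sum() / (n - 2)
                    + a.sum() / ((n - 1) * (n - 2))
                )
    return A


def naive_dcor_sq(x, y):
    """From-scratch double-loop squared bias-corrected distance correlation
    (oracle, independent of the library implementation)."""
    n = len(x)
    A, B = naive_u_centered(x), naive_u_centered(y)

    def up(P, Q):
        s = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    s += P[i, j] * Q[i, j]
        return s / (n * (n - 3))

    return up(A, B) / np.sqrt(up(A, A) * up(B, B))
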