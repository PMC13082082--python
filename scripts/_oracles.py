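"""Independent double-loop oracles used by the acceptance script."""

import numpy as np


def naive_u_centered(x):
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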