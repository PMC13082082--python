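"""Explicitly nonlinear functional connectivity (ENL FC) estimation.

Four whole-brain dependence matrices are computed from one scan's Z-scored
voxel time series:

* ``LIN``  — Pearson correlation, the standard linear FC.
* ``NL``   — bias-corrected distance correlation: the squared U-statistic
  estimator is truncated at zero and square-rooted, giving a dependence
  measure sensitive to linear *and* nonlinear coupling, with the positive
  small-sample bias of the naive estimator removed.
* ``NULL_ENL`` — the closed-form distance correlation a voxel pair *would*
  exhibit if it were bivariate Gaussian with the observed Pearson r: the
  counterfactual, linear-only dependence mapped into distance-correlation
  space.
* ``ENL``  — NL minus NULL_ENL: the dependence that supersedes what
  Gaussianity explains, i.e. the explicitly nonlinear part.

The key algebraic object is the U-centered Euclidean distance matrix; the
inner product of two U-centered matrices over off-diagonal cells, scaled by
1/(n(n-3)), is the unbiased squared distance covariance. Because of the
U-centering, every row and column of such a matrix sums to zero and the
squared distance correlation of independent series is *mean-zero* (it may be
negative by chance).

The whole-brain path flattens each voxel's U-centered matrix and obtains all
pairwise inner products as one Gram matrix product, processed in voxel
blocks; a streaming numba kernel with O(n) memory handles single pairs at
sample sizes where an n x n matrix is not materializable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .errors import ContractError, DegenerateVoxelError, DomainError, SampleSizeError

__all__ = [
    "TimeSeriesMatrix",
    "FCMatrix",
    "UCenteredDistanceMatrix",
    "zscore_timeseries",
    "pearson_fc",
    "u_centered_distances",
    "u_product",
    "bias_corrected_dcor_sq",
    "nl_fc_matrix",
    "gaussian_null_value",
    "enl_fc_matrix",
]

FCKind = Literal["LIN", "NL", "NULL_ENL", "ENL"]

#: denominator of the Gaussian-null closed form, 1 + pi/3 - sqrt(3)
_NULL_DENOM = 1.0 + np.pi / 3.0 - np.sqrt(3.0)


@dataclass
class TimeSeriesMatrix:
    """One scan's variance-normalized voxel time series.

    ``values`` is timepoints (n) x voxels (v); every column has mean 0 and
    sample standard deviation 1 (ddof=1). ``voxel_index`` optionally maps
    voxel columns back to 3-D mask coordinates (v x 3 integer array).
    """

    values: np.ndarray
    voxel_index: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        if self.n < 4:
            raise SampleSizeError(f"need n >= 4 timepoints, got {self.n}")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("time series contain non-finite values")
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=1)
        if np.any(np.abs(mu) > atol) or np.any(np.abs(sd - 1.0) > 1e-6):
            raise ContractError("time series are not Z-scored per voxel")


@dataclass
class UCenteredDistanceMatrix:
    """U-centered Euclidean distance matrix of one voxel's time series."""

    matrix: np.ndarray
    source_voxel: int = -1


@dataclass
class FCMatrix:
    """A symmetric voxel x voxel dependence matrix tagged with its kind."""

    values: np.ndarray
    kind: FCKind
    n_timepoints: int
    voxel_index: np.ndarray | None = field(default=None, repr=False)

    @property
    def v(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError("FC matrix must be square")
        if np.abs(a - a.T).max() > 1e-10:
            raise ContractError("FC matrix must be symmetric")
        d = np.diag(a)
        if self.kind == "ENL":
            if np.abs(d).max() > 1e-12:
                raise ContractError("ENL diagonal must be 0")
        else:
            if np.abs(d - 1.0).max() > 1e-10:
                raise ContractError(f"{self.kind} diagonal must be 1")
        if self.kind == "LIN" and (a.min() < -1 - 1e-10 or a.max() > 1 + 1e-10):
            raise ContractError("LIN entries must lie in [-1, 1]")
        if self.kind in ("NL", "NULL_ENL") and (a.min() < -1e-12 or a.max() > 1 + 1e-10):
            raise ContractError(f"{self.kind} entries must lie in [0, 1]")


def zscore_timeseries(raw: np.ndarray, voxel_index: np.ndarray | None = None) -> TimeSeriesMatrix:
    """Z-score each voxel column to mean 0 / sample sd 1 (ddof=1).

    Idempotent on already-normalized input. A constant column is rejected
    with :class:`DegenerateVoxelError` naming the offending voxel rather
    than silently masked.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ContractError("expected a 2-D (timepoints x voxels) array")
    n = raw.shape[0]
    if n < 4:
        raise SampleSizeError(f"need n >= 4 timepoints, got {n}")
    if not np.all(np.isfinite(raw)):
        raise ContractError("time series contain non-finite values")
    sd = raw.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 1e-300)
    if bad.size:
        raise DegenerateVoxelError(bad[0])
    z = (raw - raw.mean(axis=0)) / sd
    return TimeSeriesMatrix(values=z, voxel_index=voxel_index)


def pearson_fc(ts: TimeSeriesMatrix) -> FCMatrix:
    """Linear FC: r(x, y) = (1/(n-1)) * sum_i x_i y_i on Z-scored columns."""
    ts.validate()
    z = ts.values
    n = ts.n
    r = (z.T @ z) / (n - 1)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, kind="LIN", n_timepoints=n, voxel_index=ts.voxel_index)


def u_centered_distances(x: np.ndarray, source_voxel: int = -1) -> UCenteredDistanceMatrix:
    """U-centered Euclidean distance matrix of a scalar series.

    Off-diagonal: A_ij = a_ij - row_i/(n-2) - col_j/(n-2) + grand/((n-1)(n-2))
    with a_ij = |x_i - x_j|; the diagonal is exactly zero. Every row and
    column of the result sums to zero.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n = x.size
    if n < 4:
        raise SampleSizeError(f"U-centering requires n >= 4, got {n}")
    a = np.abs(x[:, None] - x[None, :])
    row = a.sum(axis=1)
    grand = row.sum()
    A = a - row[:, None] / (n - 2) - row[None, :] / (n - 2) + grand / ((n - 1) * (n - 2))
    np.fill_diagonal(A, 0.0)
    return UCenteredDistanceMatrix(matrix=A, source_voxel=source_voxel)


def u_product(A: np.ndarray, B: np.ndarray) -> float:
    """Unbiased squared distance covariance from two U-centered matrices:
    (1/(n(n-3))) * sum_{i != j} A_ij B_ij. Mean-zero under independence."""
    n = A.shape[0]
    if n < 4:
        raise SampleSizeError("u_product requires n >= 4")
    # diagonals are zero, so the full elementwise sum equals the i != j sum
    return float(np.sum(A * B)) / (n * (n - 3))


@njit(cache=True)
def _pair_moments(x, y):  # pragma: no cover - numba kernel
    """Streaming pass over all pairs: inner products and row sums of the raw
    distance matrices of x and y, in O(n) memory."""
    n = x.size
    s_ab = 0.0
    s_aa = 0.0
    s_bb = 0.0
    ra = np.zeros(n)
    rb = np.zeros(n)
    for i in range(n):
        xi = x[i]
        yi = y[i]
        for j in range(i + 1, n):
            da = abs(xi - x[j])
            db = abs(yi - y[j])
            s_ab += 2.0 * da * db
            s_aa += 2.0 * da * da
            s_bb += 2.0 * db * db
            ra[i] += da
            ra[j] += da
            rb[i] += db
            rb[j] += db
    return s_ab, s_aa, s_bb, ra, rb


def _u_stat_from_moments(s: float, r1: np.ndarray, r2: np.ndarray, n: int) -> float:
    """U-centered inner product from raw-distance moments:

    sum_{i!=j} A_ij B_ij = [ab] - (2/(n-2)) * sum_i ra_i rb_i
                           + ga * gb / ((n-1)(n-2))
    scaled by 1/(n(n-3)).
    """
    g1 = float(r1.sum())
    g2 = float(r2.sum())
    dot = float(np.dot(r1, r2))
    total = s - 2.0 * dot / (n - 2) + g1 * g2 / ((n - 1) * (n - 2))
    return total / (n * (n - 3))


# above ~this n, materializing an n x n matrix is wasteful; stream instead
_STREAM_N = 4000


def bias_corrected_dcor_sq(x: np.ndarray, y: np.ndarray) -> float:
    """Squared bias-corrected distance correlation R^2_n(x, y).

    R^2_n = U^2_n(x,y) / sqrt(U^2_n(x,x) U^2_n(y,y)); may be negative by
    sampling variation, and is <= 1. Large series are handled by a streaming
    O(n^2)-time / O(n)-memory kernel.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ContractError("series must have equal length")
    n = x.size
    if n < 4:
        raise SampleSizeError(f"need n >= 4, got {n}")
    if n > _STREAM_N:
        s_ab, s_aa, s_bb, ra, rb = _pair_moments(x, y)
        uxy = _u_stat_from_moments(s_ab, ra, rb, n)
        uxx = _u_stat_from_moments(s_aa, ra, ra, n)
        uyy = _u_stat_from_moments(s_bb, rb, rb, n)
    else:
        A = u_centered_distances(x).matrix
        B = u_centered_distances(y).matrix
        uxy = u_product(A, B)
        uxx = u_product(A, A)
        uyy = u_product(B, B)
    if uxx <= 0 or uyy <= 0:
        bad = 0 if uxx <= 0 else 1
        raise DegenerateVoxelError(bad, "degenerate series: nonpositive self distance covariance")
    return min(uxy / np.sqrt(uxx * uyy), 1.0)


def _flattened_u_matrices(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel U-centered distance matrices, flattened to (v, n*n), plus the
    per-voxel self U-statistics U^2_n(x,x)."""
    n, v = z.shape
    M = np.empty((v, n * n))
    self_u = np.empty(v)
    for j in range(v):
        A = u_centered_distances(z[:, j], source_voxel=j).matrix
        M[j] = A.ravel()
        self_u[j] = u_product(A, A)
    return M, self_u


def _dcor_sq_matrix(ts: TimeSeriesMatrix, block_size: int = 64) -> np.ndarray:
    """All-pairs squared bias-corrected distance correlation, via blockwise
    Gram products of flattened U-centered matrices."""
    z = np.ascontiguousarray(ts.values)
    n, v = z.shape
    M, self_u = _flattened_u_matrices(z)
    bad = np.flatnonzero(self_u <= 0)
    if bad.size:
        raise DegenerateVoxelError(bad[0], f"voxel {bad[0]} has nonpositive self distance covariance")
    scale = 1.0 / (n * (n - 3))
    R = np.empty((v, v))
    for i0 in range(0, v, block_size):
        i1 = min(i0 + block_size, v)
        for j0 in range(i0, v, block_size):
            j1 = min(j0 + block_size, v)
            G = (M[i0:i1] @ M[j0:j1].T) * scale
            R[i0:i1, j0:j1] = G
            R[j0:j1, i0:i1] = G.T
    denom = np.sqrt(np.outer(self_u, self_u))
    R /= denom
    np.minimum(R, 1.0, out=R)
    return R


def nl_fc_matrix(ts: TimeSeriesMatrix, block_size: int = 64) -> FCMatrix:
    """Nonlinear FC: sqrt of the zero-truncated squared bias-corrected
    distance correlation, all voxel pairs; diagonal 1."""
    ts.validate()
    R = _dcor_sq_matrix(ts, block_size=block_size)
    nl = np.sqrt(np.maximum(R, 0.0))
    nl = (nl + nl.T) / 2.0
    np.fill_diagonal(nl, 1.0)
    return FCMatrix(values=nl, kind="NL", n_timepoints=ts.n, voxel_index=ts.voxel_index)


def gaussian_null_value(r):
    """Distance correlation of a bivariate Gaussian pair with Pearson
    correlation r, on the same (square-root) scale as NL FC.

    The closed form

        (r asin r + sqrt(1-r^2) - r asin(r/2) - sqrt(4-r^2) + 1)
        / (1 + pi/3 - sqrt(3))

    is the *squared* distance correlation of a bivariate normal; its square
    root is returned so that ENL = NL - NULL_ENL vanishes for Gaussian pairs
    on matched scales. Even in r, monotone in |r|, 0 at r=0 and 1 at |r|=1.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise DomainError("Pearson correlation outside [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    num = (
        r * np.arcsin(r)
        + np.sqrt(1.0 - r * r)
        - r * np.arcsin(r / 2.0)
        - np.sqrt(4.0 - r * r)
        + 1.0
    )
    sq = np.clip(num / _NULL_DENOM, 0.0, 1.0)
    out = np.sqrt(sq)
    return float(out) if out.ndim == 0 else out


def enl_fc_matrix(
    ts: TimeSeriesMatrix, block_size: int = 64
) -> tuple[FCMatrix, FCMatrix, FCMatrix, FCMatrix]:
    """Full ENL decomposition of one scan: (LIN, NL, NULL_ENL, ENL).

    ENL = NL - NULL_ENL elementwise, diagonal forced to 0; signed values are
    kept (only the squared distance correlation is truncated, inside NL).
    For jointly Gaussian pairs ENL is ~0 at large n; for purely nonlinear
    coupling (e.g. y = x^2) LIN is ~0 while ENL is clearly positive.
    """
    lin = pearson_fc(ts)
    nl = nl_fc_matrix(ts, block_size=block_size)
    null_vals = gaussian_null_value(lin.values)
    np.fill_diagonal(null_vals, 1.0)
    null = FCMatrix(values=null_vals, kind="NULL_ENL", n_timepoints=ts.n, voxel_index=ts.voxel_index)
    enl_vals = nl.values - null.values
    np.fill_diagonal(enl_vals, 0.0)
    enl = FCMatrix(values=enl_vals, kind="ENL", n_timepoints=ts.n, voxel_index=ts.voxel_index)
    return lin, nl, null, enl
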