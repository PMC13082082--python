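"""Spatial comparison statistics for matched network pairs.

Voxelwise paired t maps with Benjamini-Hochberg FDR control, permutation
tests (sign-flip for paired designs, relabeling for independent ones),
Hedges's g effect sizes, and McNemar's test on the four-outcome
significance contingency used to compare branch sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import (
    ContractError,
    DomainError,
    InsufficientSampleError,
    ParameterError,
    UndefinedTestError,
)

__all__ = [
    "VoxelStatMap",
    "EffectSize",
    "paired_t_map_fdr",
    "permutation_test",
    "hedges_g",
    "bh_fdr",
    "mcnemar_test",
    "supra_threshold_union",
]

Design = Literal["paired", "independent"]


@dataclass
class VoxelStatMap:
    """Per-voxel test results inside a test mask.

    Arrays are full-length (all voxels); entries outside ``test_mask`` are
    NaN. ``significant`` flags q < alpha voxels.
    """

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    test_mask: np.ndarray
    alpha: float = 0.05


@dataclass
class EffectSize:
    hedges_g: float
    design: Design
    difference: float


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(p_(j) * m / j, 1) on the sorted scale; input
    order is preserved, q >= p always.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.reshape(p.shape)


def supra_threshold_union(z_a: np.ndarray, z_b: np.ndarray, z_threshold: float = 1.96) -> np.ndarray:
    """Voxels significantly contributing to either group map: the union of
    the two |Z| > threshold supra-threshold sets (computed after
    peak-positive sign alignment of the Z maps)."""
    return (np.abs(z_a) > z_threshold) | (np.abs(z_b) > z_threshold)


def paired_t_map_fdr(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
) -> VoxelStatMap:
    """Two-sided paired t-test per in-mask voxel, BH-FDR across voxels.

    ``a`` and ``b`` are scans x voxels slices of the two branches'
    participant map stacks, aligned scan-for-scan.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape:
        raise ContractError("paired stacks must have identical shape")
    if not mask.any():
        raise ContractError("empty test mask")
    if a.shape[0] < 3:
        raise InsufficientSampleError("paired t-test needs at least 3 scan pairs")
    v = a.shape[1]
    t = np.full(v, np.nan)
    p = np.full(v, np.nan)
    d = a[:, mask] - b[:, mask]
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = mean / (sd / np.sqrt(n))
    # sd == 0: identical pairs give t = 0, a constant nonzero shift gives t = inf
    tt = np.where((sd == 0) & (mean == 0), 0.0, tt)
    pp = 2.0 * sps.t.sf(np.abs(tt), df=n - 1)
    pp = np.where(np.isfinite(tt), pp, 0.0)
    t[mask] = tt
    p[mask] = pp
    q = np.full(v, np.nan)
    q[mask] = bh_fdr(p[mask])
    sig = np.zeros(v, dtype=bool)
    sig[mask] = q[mask] < alpha
    return VoxelStatMap(statistic=t, p=p, q=q, significant=sig, test_mask=mask, alpha=alpha)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    design: Design = "paired",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Two-sided permutation test on the mean difference.

    Paired design permutes by random sign flips of the pair differences;
    independent design by random group relabelings. Returns
    (p, observed statistic) with the add-one correction
    p = (1 + #{|perm| >= |obs|}) / (n_perm + 1). With ``exhaustive`` (paired
    only, n <= 20) all 2^n sign patterns are enumerated and p is the exact
    tail fraction, identity permutation included.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if design == "paired":
        if a.size != b.size:
            raise ContractError("paired design requires equal lengths")
        d = a - b
        obs = float(d.mean())
        if exhaustive:
            n = d.size
            if n > 20:
                raise ParameterError("exhaustive enumeration limited to n <= 20 pairs")
            bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
            null = ((2.0 * bits - 1.0) * d).mean(axis=1)
            p = float(np.mean(np.abs(null) >= abs(obs) - 1e-15))
            return p, obs
        signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
        null = (signs * d).mean(axis=1)
    elif design == "independent":
        if a.size == 0 or b.size == 0:
            raise ContractError("independent design requires nonempty groups")
        obs = float(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = perm[: a.size].mean() - perm[a.size :].mean()
    else:
        raise ParameterError(f"unknown design {design!r}")
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-15)) / (n_perm + 1.0)
    return float(p), obs


def hedges_g(a: np.ndarray, b: np.ndarray, design: Design = "independent") -> EffectSize:
    """Hedges's g: standardized mean difference with the small-sample
    correction J = 1 - 3/(4 df - 1).

    Independent design pools the two group variances (df = n1 + n2 - 2);
    paired design standardizes by the standard deviation of the pair
    differences (df = n - 1).
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if design == "paired":
        if a.size != b.size:
            raise ContractError("paired design requires equal lengths")
        if a.size < 2:
            raise InsufficientSampleError("need >= 2 pairs")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            if np.allclose(d, 0):
                return EffectSize(hedges_g=0.0, design=design, difference=0.0)
            raise ContractError("zero variance of nonzero differences")
        df = a.size - 1
        g_unc = d.mean() / sd
        diff = float(d.mean())
    elif design == "independent":
        if a.size < 2 or b.size < 2:
            raise InsufficientSampleError("need >= 2 per group")
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        diff = float(a.mean() - b.mean())
        if sp2 == 0:
            if diff == 0:
                return EffectSize(hedges_g=0.0, design=design, difference=0.0)
            raise ContractError("zero pooled variance with nonzero difference")
        g_unc = diff / np.sqrt(sp2)
    else:
        raise ParameterError(f"unknown design {design!r}")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    return EffectSize(hedges_g=float(J * g_unc), design=design, difference=diff)


def mcnemar_test(
    n_both: int,
    n_first_only: int,
    n_second_only: int,
    n_neither: int,
    exact_threshold: int = 25,
) -> tuple[float, float, float]:
    """Two-sided McNemar's test on discordant counts.

    With b = first-only and c = second-only discordant counts:
    chi2 = (|b - c| - 1)^2 / (b + c) (continuity corrected); the p-value is
    the exact two-sided binomial probability when b + c < ``exact_threshold``
    and the chi-square tail otherwise. The odds ratio b / c expresses the
    first branch's advantage (+inf sentinel when c = 0).
    """
    b, c = int(n_first_only), int(n_second_only)
    if min(n_both, b, c, n_neither) < 0:
        raise DomainError("contingency counts must be nonnegative")
    if b + c == 0:
        raise UndefinedTestError("no discordant pairs: McNemar's test undefined")
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    if b + c < exact_threshold:
        k = min(b, c)
        p = float(min(1.0, 2.0 * sps.binom.cdf(k, b + c, 0.5)))
        if b == c:
            p = 1.0
    else:
        p = float(sps.chi2.sf(chi2, df=1))
    odds = float("inf") if c == 0 else b / c
    return float(chi2), p, odds
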