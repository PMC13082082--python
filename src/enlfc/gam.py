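"""Voxelwise developmental trajectory modeling.

Each voxel's participant-level network weight is modeled against corrected
age with a generalized additive model,

    weight ~ f(age) + sex + scanner + mean_fd + (1 | participant),

where f is a penalized thin-plate regression spline (integrated squared
second derivative penalty, basis dimension k=10) and the participant random
intercept enters as a ridge-penalized block of indicator columns. Both smoothing parameters are chosen
by a Laplace marginal-likelihood criterion evaluated on a log-spaced grid
(ML by default, which guards better against spurious wiggliness under a
linear truth; REML is selectable).

The effective degrees of freedom (EDF) of the age smooth quantify trajectory
complexity: EDF ~ 1 is an (approximately) linear trajectory, EDF >= 3 a
highly nonlinear one. The smooth is tested with an approximate Wald F test
(numerator df = smooth EDF, denominator df = n - total EDF), whose
calibration is verified by null simulation rather than assumed.

Because the design matrix depends only on the scan metadata, one
:class:`VoxelGAM` is built per network and reused across voxels; per-voxel
work reduces to cheap linear solves against pre-factorized penalized normal
equations for every grid point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, InsufficientSampleError, ParameterError
from .stats import bh_fdr, hedges_g, mcnemar_test, permutation_test

__all__ = [
    "VoxelGAM",
    "GAMFit",
    "GAMVoxelResult",
    "SensitivityRow",
    "fit_voxel_gam",
    "network_age_maps",
    "compare_edf",
    "compare_sensitivity",
]

META_COLUMNS = ("participant_id", "corrected_age", "sex", "scanner", "mean_fd")


# ---------------------------------------------------------------------------
# spline basis


def _tprs(x: np.ndarray, k: int) -> dict:
    """1-D thin-plate regression spline of basis dimension k.

    The full thin-plate spline f(x) = sum_i d_i |x - x_i|^3 + b0 + b1 x
    (integrated-squared-second-derivative penalty, null space {1, x}) is
    rank-reduced by keeping the k leading eigenvectors of the radial matrix
    E_ij = |x_i - x_j|^3 and absorbing the two side conditions T'd = 0.
    Returns the penalized design block (n x (k-2)), its (diagonalized)
    penalty eigenvalues, and the maps needed to evaluate the smooth at new
    ages. The penalty null space reduces to the linear-in-age direction, so
    a fully penalized smooth is exactly a straight line.
    """
    n = x.size
    if k < 4:
        raise ParameterError(f"basis dimension k={k} too small")
    if k > n:
        raise ParameterError(f"basis dimension k={k} exceeds number of scans {n}")
    # work on unit-range ages so basis columns and penalty share a scale
    x0, span = float(x.min()), max(float(np.ptp(x)), 1e-12)
    u = (x - x0) / span
    E = np.abs(u[:, None] - u[None, :]) ** 3
    evals, evecs = np.linalg.eigh(E)
    keep = np.argsort(-np.abs(evals))[:k]
    U, D = evecs[:, keep], evals[keep]
    T = np.column_stack([np.ones(n), u])
    _, _, Vt = np.linalg.svd(T.T @ U)
    Zc = Vt[2:].T  # k x (k-2), null space of the side conditions
    B_raw = U @ (D[:, None] * Zc)  # = E @ U @ Zc evaluated at the data
    S = Zc.T @ (D[:, None] * Zc)  # = Zc' D Zc, PSD on the constrained space
    S = (S + S.T) / 2.0
    # unit-RMS columns, penalty transformed to match
    scale = np.sqrt(np.mean(B_raw**2, axis=0))
    scale[scale == 0] = 1.0
    B_raw = B_raw / scale
    S = S / np.outer(scale, scale)
    S /= np.abs(S).max()  # scale-free penalty so the lambda grid is portable
    w, Ur = np.linalg.eigh(S)
    pos = w > w.max() * 1e-10
    B_range = B_raw @ Ur[:, pos]
    return {
        "B_range": B_range,
        "w_range": w[pos],
        # eta-distances (on unit-range ages) @ pred_map = range basis
        "pred_map": (U @ Zc / scale) @ Ur[:, pos],
        "x_train": u.copy(),
        "x0": x0,
        "span": span,
    }


# ---------------------------------------------------------------------------
# fit containers


@dataclass
class GAMFit:
    """One voxel's penalized additive fit summary."""

    F: float
    edf: float
    p: float
    edf_total: float
    sigma2: float
    lambda_smooth: float
    lambda_ridge: float
    beta: np.ndarray = field(repr=False)
    converged: bool = True


@dataclass
class GAMVoxelResult:
    """Per-voxel developmental fit summaries for one network.

    Full-length arrays with NaN outside the tested mask; ``q`` is BH-FDR
    adjusted across the network's tested voxels; ``significant`` flags
    q < alpha.
    """

    F: np.ndarray
    edf: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    test_mask: np.ndarray
    n_failed: int = 0
    alpha: float = 0.05


@dataclass
class SensitivityRow:
    """Four-outcome voxel contingency between branches plus McNemar's test."""

    n_both: int
    n_enl_only: int
    n_lin_only: int
    n_neither: int
    chi2: float
    p: float
    odds_ratio: float
    significant_bonferroni: bool
    alpha: float
    defined: bool = True
    reason: str | None = None


# ---------------------------------------------------------------------------
# the model


class VoxelGAM:
    """Penalized additive model with a shared design across voxels.

    Parameters
    ----------
    meta:
        Scan metadata table with columns ``participant_id``,
        ``corrected_age`` (days), ``sex``, ``scanner``, ``mean_fd`` (mm);
        one row per scan, aligned with the weight vectors passed to
        :meth:`fit`.
    basis_dim:
        thin-plate spline basis dimension for the age smooth (default 10);
        the age smooth then carries basis_dim - 1 coefficients (one linear
        plus basis_dim - 2 penalized curvature directions).
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        basis_dim: int = 10,
        criterion: str = "ML",
        lambda_smooth_grid: np.ndarray | None = None,
        lambda_ridge_grid: np.ndarray | None = None,
    ):
        if criterion not in ("ML", "REML"):
            raise ParameterError("criterion must be 'ML' or 'REML'")
        self.criterion = criterion
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ContractError(f"metadata missing columns {missing}")
        n = len(meta)
        if n < 20:
            raise InsufficientSampleError(f"need >= 20 scans for GAM fitting, got {n}")
        self.meta = meta.reset_index(drop=True)
        self.n = n
        age = self.meta["corrected_age"].to_numpy(dtype=np.float64)

        # --- fixed-effect columns: intercept + sex/scanner dummies + motion
        cols = [np.ones(n)]
        self.dropped_terms: list[str] = []
        for cat in ("sex", "scanner"):
            levels = pd.unique(self.meta[cat])
            if len(levels) < 2:
                self.dropped_terms.append(cat)
                warnings.warn(f"covariate {cat!r} has a single level and was dropped")
                continue
            for lev in levels[1:]:
                cols.append((self.meta[cat] == lev).to_numpy(dtype=np.float64))
        fd = self.meta["mean_fd"].to_numpy(dtype=np.float64)
        cols.append((fd - fd.mean()) / (fd.std(ddof=1) if fd.std(ddof=1) > 0 else 1.0))
        X_fixed = np.column_stack(cols)
        self.p_fixed = X_fixed.shape[1]

        # --- ridge random intercepts, one indicator column per participant
        pid = pd.Categorical(self.meta["participant_id"])
        self.participants = list(pid.categories)
        Z = np.zeros((n, len(self.participants)))
        Z[np.arange(n), pid.codes] = 1.0
        self.p_ridge = Z.shape[1]

        # --- age smooth: thin-plate regression spline, linear null space as
        # an unpenalized column plus diagonally penalized range directions
        self.basis_dim = basis_dim
        self.age_min, self.age_max = float(age.min()), float(age.max())
        tp = _tprs(age, basis_dim)
        self._age_mean = float(age.mean())
        B_null = (age - self._age_mean)[:, None]
        B_range = tp["B_range"] - tp["B_range"].mean(axis=0, keepdims=True)
        self._range_colmeans = tp["B_range"].mean(axis=0)
        self._pred_map = tp["pred_map"]
        self._x_train = tp["x_train"]
        self._x0, self._span = tp["x0"], tp["span"]
        self._w_range = tp["w_range"]
        self._smooth_rank = int(self._w_range.size)
        self.p_smooth = 1 + self._smooth_rank

        # column order: fixed | smooth null | ridge random intercepts | smooth range
        self.X = np.column_stack([X_fixed, B_null, Z, B_range])
        self.p = self.X.shape[1]
        p_f = self.p_fixed + B_null.shape[1]
        self._p_unpen = p_f
        self._ridge_sl = slice(p_f, p_f + self.p_ridge)
        self._range_sl = slice(p_f + self.p_ridge, self.p)
        self._smooth_idx = np.concatenate(
            [np.arange(self.p_fixed, p_f), np.arange(p_f + self.p_ridge, self.p)]
        )
        self._log_det_S = float(np.sum(np.log(self._w_range)))
        # unpenalized dimension: fixed effects + the smooth's penalty null space
        self._M_p = p_f

        self.XtX = self.X.T @ self.X
        if lambda_smooth_grid is None:
            lambda_smooth_grid = np.logspace(-4, 8, 25)
        if lambda_ridge_grid is None:
            lambda_ridge_grid = np.logspace(-2, 4, 13)
        self._grid = [(ls, lr) for ls in lambda_smooth_grid for lr in lambda_ridge_grid]
        self._prepare_grid()

    # -- precomputation ----------------------------------------------------
    def _penalty_diag(self, lam_s: float, lam_r: float) -> np.ndarray:
        d = np.zeros(self.p)
        d[self._ridge_sl] = lam_r
        d[self._range_sl] = lam_s * self._w_range
        return d

    def _prepare_grid(self) -> None:
        self._chol = []
        self._logdet_score = []  # |X'X+P| for REML, penalized block only for ML
        self._logdet_P = []
        self._edf_diag = []
        self._Hinv = []
        pu = self._p_unpen
        for lam_s, lam_r in self._grid:
            H = self.XtX + np.diag(self._penalty_diag(lam_s, lam_r))
            L = np.linalg.cholesky(H)
            Hinv = np.linalg.inv(H)
            self._chol.append(L)
            self._Hinv.append(Hinv)
            if self.criterion == "REML":
                logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            else:
                # ML: determinant of the penalized block alone, |X_p'X_p + P_p|
                Hpp = H[pu:, pu:]
                logdet = 2.0 * float(np.sum(np.log(np.diag(np.linalg.cholesky(Hpp)))))
            self._logdet_score.append(logdet)
            self._logdet_P.append(
                self._smooth_rank * np.log(lam_s)
                + self._log_det_S
                + self.p_ridge * np.log(lam_r)
            )
            self._edf_diag.append(np.diag(Hinv @ self.XtX).copy())

    # -- fitting -----------------------------------------------------------
    def fit(self, y: np.ndarray) -> GAMFit:
        """Fit one voxel's weights; smoothing parameters chosen by the
        configured marginal-likelihood criterion on the precomputed grid."""
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != self.n:
            raise ContractError("weight vector length does not match metadata rows")
        Xty = self.X.T @ y
        yty = float(y @ y)
        best = (np.inf, -1, None)
        for g, (lam_s, lam_r) in enumerate(self._grid):
            L = self._chol[g]
            beta = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
            rss = yty - 2.0 * beta @ Xty + beta @ self.XtX @ beta
            pen = float(np.sum(self._penalty_diag(lam_s, lam_r) * beta**2))
            dp = max(rss + pen, 1e-300)
            # ML: n in the profiled-variance term; REML corrects for the
            # unpenalized dimension M_p (fixed effects + smooth null space)
            nmp = self.n if self.criterion == "ML" else self.n - self._M_p
            score = (
                0.5 * nmp * np.log(dp / nmp)
                + 0.5 * self._logdet_score[g]
                - 0.5 * self._logdet_P[g]
            )
            if score < best[0]:
                best = (score, g, beta)
        _, g, beta = best
        lam_s, lam_r = self._grid[g]
        rss = yty - 2.0 * beta @ Xty + beta @ self.XtX @ beta
        edf_diag = self._edf_diag[g]
        edf_total = float(edf_diag.sum())
        edf_smooth = float(edf_diag[self._smooth_idx].sum())
        resid_df = max(self.n - edf_total, 1.0)
        sigma2 = max(rss, 0.0) / resid_df

        # approximate Wald F test on the smooth block (null + range columns)
        bs = beta[self._smooth_idx]
        Vb = sigma2 * self._Hinv[g][np.ix_(self._smooth_idx, self._smooth_idx)]
        try:
            stat = float(bs @ np.linalg.solve(Vb, bs))
        except np.linalg.LinAlgError:
            stat = float(bs @ np.linalg.pinv(Vb) @ bs)
        nu = max(edf_smooth, 1e-3)
        F = stat / nu
        p = float(sps.f.sf(F, nu, resid_df))
        return GAMFit(
            F=F,
            edf=edf_smooth,
            p=p,
            edf_total=edf_total,
            sigma2=sigma2,
            lambda_smooth=lam_s,
            lambda_ridge=lam_r,
            beta=beta,
        )

    def smooth_curve(self, fit: GAMFit, ages: np.ndarray) -> np.ndarray:
        """Partial effect of age (centered smooth) at the given ages."""
        ages = np.asarray(ages, dtype=np.float64).ravel()
        u = (ages - self._x0) / self._span
        eta = np.abs(u[:, None] - self._x_train[None, :]) ** 3
        B_range = eta @ self._pred_map - self._range_colmeans
        lin = (ages - self._age_mean) * fit.beta[self._smooth_idx][0]
        return lin + B_range @ fit.beta[self._range_sl]


def fit_voxel_gam(weights: np.ndarray, meta: pd.DataFrame, basis_dim: int = 10) -> GAMFit:
    """Convenience single-voxel fit; see :class:`VoxelGAM`."""
    return VoxelGAM(meta, basis_dim=basis_dim).fit(weights)


def network_age_maps(
    stack: np.ndarray,
    meta: pd.DataFrame,
    network_mask: np.ndarray,
    basis_dim: int = 10,
    alpha: float = 0.05,
    model: VoxelGAM | None = None,
) -> GAMVoxelResult:
    """Voxelwise GAM over one network's supra-threshold voxels.

    ``stack`` is scans x voxels (one component's participant-level weights);
    ``network_mask`` selects the voxels that significantly contribute to the
    group map. BH-FDR is applied across the network's tested voxels.
    """
    stack = np.asarray(stack, dtype=np.float64)
    mask = np.asarray(network_mask, dtype=bool)
    if not mask.any():
        raise ContractError("empty network mask")
    if stack.shape[0] != len(meta):
        raise ContractError("stack scans do not match metadata rows")
    v = stack.shape[1]
    gam = model if model is not None else VoxelGAM(meta, basis_dim=basis_dim)
    F = np.full(v, np.nan)
    edf = np.full(v, np.nan)
    p = np.full(v, np.nan)
    failed = 0
    idx = np.flatnonzero(mask)
    for j in idx:
        try:
            fit = gam.fit(stack[:, j])
        except Exception:
            failed += 1
            continue
        F[j], edf[j], p[j] = fit.F, fit.edf, fit.p
    q = np.full(v, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    sig = np.zeros(v, dtype=bool)
    sig[ok] = q[ok] < alpha
    return GAMVoxelResult(F=F, edf=edf, p=p, q=q, significant=sig, test_mask=mask, n_failed=failed, alpha=alpha)


def compare_edf(
    enl_edf: np.ndarray,
    lin_edf: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05 / 15,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Two-sided independent-samples permutation comparison of the EDF values
    of significant voxels in the two branches, with Hedges's g; the
    Bonferroni decision is taken at ``alpha``."""
    enl_edf = np.asarray(enl_edf, dtype=np.float64).ravel()
    lin_edf = np.asarray(lin_edf, dtype=np.float64).ravel()
    if enl_edf.size == 0 or lin_edf.size == 0:
        return {
            "skipped": True,
            "reason": "no significant voxels in one branch",
            "n_enl": int(enl_edf.size),
            "n_lin": int(lin_edf.size),
        }
    p, diff = permutation_test(enl_edf, lin_edf, design="independent", n_perm=n_perm, seed=seed)
    g = hedges_g(enl_edf, lin_edf, design="independent")
    return {
        "skipped": False,
        "difference": diff,
        "p": p,
        "hedges_g": g.hedges_g,
        "significant_bonferroni": bool(p < alpha),
        "alpha": alpha,
        "n_enl": int(enl_edf.size),
        "n_lin": int(lin_edf.size),
    }


def compare_sensitivity(
    enl_result: GAMVoxelResult,
    lin_result: GAMVoxelResult,
    common_mask: np.ndarray | None = None,
    alpha: float = 0.05 / 15,
) -> SensitivityRow:
    """Four-outcome voxel tally (both / ENL-only / LIN-only / neither) on the
    voxels tested by both branches, with two-sided McNemar's test; the odds
    ratio ENL-only / LIN-only > 1 expresses an ENL sensitivity advantage."""
    if common_mask is None:
        common_mask = enl_result.test_mask & lin_result.test_mask
    common_mask = np.asarray(common_mask, dtype=bool)
    e = enl_result.significant[common_mask]
    l = lin_result.significant[common_mask]
    n_both = int(np.sum(e & l))
    n_enl = int(np.sum(e & ~l))
    n_lin = int(np.sum(~e & l))
    n_neither = int(np.sum(~e & ~l))
    try:
        chi2, p, odds = mcnemar_test(n_both, n_enl, n_lin, n_neither)
    except Exception as exc:
        return SensitivityRow(
            n_both=n_both, n_enl_only=n_enl, n_lin_only=n_lin, n_neither=n_neither,
            chi2=float("nan"), p=float("nan"), odds_ratio=float("nan"),
            significant_bonferroni=False, alpha=alpha, defined=False, reason=str(exc),
        )
    return SensitivityRow(
        n_both=n_both, n_enl_only=n_enl, n_lin_only=n_lin, n_neither=n_neither,
        chi2=chi2, p=p, odds_ratio=odds,
        significant_bonferroni=bool(p < alpha), alpha=alpha,
    )
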