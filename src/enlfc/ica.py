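"""Connectivity-domain group ICA with stability analysis.

Networks are discovered from stacks of per-scan FC matrices rather than raw
time series: each voxel's whole-brain connectivity profile (one row of the
FC matrix) is an observation, so independent components are spatial maps
over voxels. The pipeline mirrors standard group spatial ICA practice:

1. scan-level PCA (default k=30) denoises each scan's FC matrix;
2. the reduced scans are concatenated along the feature axis and a group
   PCA (default k=20) yields one voxels x k data set per branch;
3. natural-gradient Infomax ICA is run many times (default 100) with random
   initialization and observation bootstrapping, and the runs are clustered
   (average-linkage agglomeration on 1 - |correlation|) to obtain stable
   components and their ICASSO quality index
   IQ = mean intra-cluster similarity - mean extra-cluster similarity;
4. components are classified as networks (peak in gray matter, sufficient
   mask overlap, IQ above threshold), greedily matched across branches on
   absolute spatial correlation, and finally back-projected to each scan by
   group-information-guided ICA (GIG-ICA): per-scan sources that maximize
   non-Gaussianity subject to similarity with the group reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import AlignmentError, ContractError, ParameterError
from .fc import FCMatrix

__all__ = [
    "PCABasis",
    "ComponentSet",
    "ICASSOResult",
    "NetworkLabelTable",
    "MatchTable",
    "ParticipantMapStack",
    "scan_level_pca",
    "group_pca",
    "infomax_ica",
    "icasso",
    "components_from_icasso",
    "classify_components",
    "greedy_match_networks",
    "gig_backreconstruct",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class PCABasis:
    """PCA reduction of connectivity data.

    ``loadings`` are feature-space directions (features x k, orthonormal
    columns); ``scores`` are the reduced data (voxels x k); ``mean`` is the
    feature mean removed before projection.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    level: Literal["scan", "group"]
    k: int
    mean: np.ndarray | None = None

    def validate(self) -> None:
        ev = self.explained_variance
        if np.any(np.diff(ev) > 1e-10) or np.any(ev < -1e-12):
            raise ContractError("explained_variance must be nonnegative, descending")
        G = self.loadings.T @ self.loadings
        if np.abs(G - np.eye(self.k)).max() > 1e-8:
            raise ContractError("loadings columns must be orthonormal")


@dataclass
class ComponentSet:
    """Group-level spatial components.

    ``spatial_maps`` is components x voxels; ``z_maps`` are the same maps
    Z-scored across voxels with the sign convention that each component's
    peak-|Z| voxel is positive.
    """

    spatial_maps: np.ndarray
    z_maps: np.ndarray
    mixing: np.ndarray
    model_order: int
    branch: Literal["ENL", "LIN"] = "ENL"

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def v(self) -> int:
        return self.spatial_maps.shape[1]


@dataclass
class ICASSOResult:
    """Stability analysis over repeated randomized ICA runs."""

    run_components: np.ndarray  # (n_runs * k) x voxels
    cluster_assignment: np.ndarray  # cluster id per run-component, 0-based
    iq: np.ndarray  # per cluster, descending order of cluster id
    centrotypes: np.ndarray  # clusters x voxels
    n_runs: int
    convergence: np.ndarray | None = None  # bool per run


@dataclass
class NetworkLabelTable:
    """Per-component network classification."""

    is_network: np.ndarray  # bool per component
    labels: list[str | None]
    rejection_reason: list[str | None]

    def network_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_network)


@dataclass
class MatchTable:
    """Greedy one-to-one matching between ENL and LIN network sets."""

    pairs: list[tuple[int, int, float]]  # (enl idx, lin idx, |r|), |r| descending
    concordant: list[bool]
    unique_enl: list[int]
    unique_lin: list[int]


@dataclass
class ParticipantMapStack:
    """Per-scan reconstructed spatial maps, scans x components x voxels."""

    maps: np.ndarray
    scan_ids: list[str]
    branch: Literal["ENL", "LIN"] = "ENL"
    similarity: np.ndarray | None = None  # scans x components, |r| to group ref
    fallback: np.ndarray | None = None  # bool, projection fallback used


# ---------------------------------------------------------------------------
# PCA stages


def _pca(data: np.ndarray, k: int, level: str) -> PCABasis:
    """PCA of ``data`` (observations x features) via SVD of the centered
    matrix; returns top-k basis with descending explained variance."""
    mean = data.mean(axis=0)
    X = data - mean
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    ev = (s**2) / (data.shape[0] - 1)
    # deterministic sign: largest-|loading| entry positive per component
    V = Vt[:k].T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = X @ V
    return PCABasis(
        loadings=V,
        scores=scores,
        explained_variance=ev[:k],
        level=level,  # type: ignore[arg-type]
        k=k,
        mean=mean,
    )


def scan_level_pca(fc: FCMatrix | np.ndarray, k: int = 30) -> PCABasis:
    """Reduce one scan's FC matrix, treating the v voxels as observations
    and their connectivity profiles as features; keeps the top-k variance
    components."""
    data = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ContractError("scan FC must be a square matrix")
    v = data.shape[0]
    if k >= v:
        raise ParameterError(f"PCA order k={k} must be < number of voxels v={v}")
    return _pca(data, k, "scan")


def group_pca(scan_bases: Sequence[PCABasis], k: int = 20) -> PCABasis:
    """Concatenate scan-level reduced data (voxels x k_scan each) along the
    feature axis and keep the top-k group components."""
    if len(scan_bases) < 2:
        raise ParameterError("group PCA needs at least 2 scans")
    v = scan_bases[0].scores.shape[0]
    for b in scan_bases:
        if b.scores.shape[0] != v:
            raise AlignmentError("scan bases have mismatched voxel dimension")
    stacked = np.concatenate([b.scores for b in scan_bases], axis=1)
    if k >= min(stacked.shape):
        raise ParameterError(f"group PCA order k={k} infeasible for stacked shape {stacked.shape}")
    return _pca(stacked, k, "group")


# ---------------------------------------------------------------------------
# Infomax ICA


def _whiten(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten rows of data (k x v): returns (whitened data, sphering matrix)."""
    X = data - data.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    K = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric sphering
    return K @ X, K


def infomax_ica(
    data: np.ndarray,
    seed: int | np.random.Generator = 0,
    bootstrap: bool = False,
    learning_rate: float = 0.1,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> dict:
    """One natural-gradient Infomax run on ``data`` (k sources x v samples).

    The logistic nonlinearity g(u) = 1/(1+exp(-u)) drives the update
    dW = lr * (I + (1 - 2 g(u)) u^T / v) W on internally whitened data; the
    learning rate anneals when the update direction oscillates. With
    ``bootstrap`` the unmixing is learned on a resample of the observations
    (columns) and then applied to the full data so run components stay
    comparable. Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ContractError("ICA input contains non-finite values")
    k, v = data.shape
    if k > v:
        raise ParameterError("need at least as many samples as sources")
    fit_data = data[:, rng.integers(0, v, size=v)] if bootstrap else data
    Xw, K = _whiten(fit_data)

    W = np.linalg.qr(rng.standard_normal((k, k)))[0]
    lr = learning_rate
    eye = np.eye(k)
    prev_dW = None
    converged = False
    for _ in range(max_iter):
        U = W @ Xw
        g = 1.0 / (1.0 + np.exp(-U))
        dW = (eye + ((1.0 - 2.0 * g) @ U.T) / v) @ W
        # anneal on oscillation of the update direction
        if prev_dW is not None and float(np.sum(dW * prev_dW)) < 0:
            lr *= 0.9
        W = W + lr * dW
        step = lr * float(np.linalg.norm(dW)) / max(float(np.linalg.norm(W)), 1e-12)
        prev_dW = dW
        if step < tol:
            converged = True
            break

    unmixing = W @ K
    sources = unmixing @ (data - data.mean(axis=1, keepdims=True))
    # unit-variance sources, deterministic sign (peak magnitude positive)
    sd = sources.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    sources = sources / sd[:, None]
    unmixing = unmixing / sd[:, None]
    flip = np.sign(sources[np.arange(k), np.abs(sources).argmax(axis=1)])
    flip[flip == 0] = 1.0
    sources *= flip[:, None]
    unmixing *= flip[:, None]
    return {"unmixing": unmixing, "sources": sources, "converged": converged}


# ---------------------------------------------------------------------------
# ICASSO


def _abs_corr(maps: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between rows, clipped to [0, 1]."""
    z = maps - maps.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    return np.clip(np.abs(z @ z.T), 0.0, 1.0)


def icasso(
    data: np.ndarray,
    n_runs: int = 100,
    model_order: int = 20,
    seed: int = 0,
    bootstrap: bool = True,
    **ica_kwargs,
) -> ICASSOResult:
    """Run Infomax ``n_runs`` times (random init, optional bootstrapping),
    cluster all run-components by average linkage on 1 - |correlation|, cut
    at ``model_order`` clusters, and compute per-cluster IQ and centrotypes.

    Clusters are ordered by descending IQ. IQ = 1 only when every member of
    a cluster is a perfect copy and uncorrelated with everything else; pure
    noise yields markedly lower values.
    """
    if n_runs < 2:
        raise ParameterError("ICASSO needs n_runs >= 2")
    k = data.shape[0]
    if model_order != k:
        raise ParameterError("model_order must equal the number of retained group components")
    master = np.random.default_rng(seed)
    run_seeds = master.spawn(n_runs)
    comps, conv = [], []
    for rs in run_seeds:
        run = infomax_ica(data, seed=rs, bootstrap=bootstrap, **ica_kwargs)
        comps.append(run["sources"])
        conv.append(run["converged"])
    all_comps = np.vstack(comps)

    sim = _abs_corr(all_comps)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=model_order, criterion="maxclust") - 1
    n_clusters = labels.max() + 1
    if n_clusters < model_order:
        warnings.warn(f"only {n_clusters} distinct clusters found for model order {model_order}")

    iq = np.empty(n_clusters)
    centro_idx = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        inside = np.flatnonzero(labels == c)
        outside = np.flatnonzero(labels != c)
        intra = sim[np.ix_(inside, inside)].mean()  # includes self-similarity 1
        extra = sim[np.ix_(inside, outside)].mean() if outside.size else 0.0
        iq[c] = intra - extra
        centro_idx[c] = inside[sim[np.ix_(inside, inside)].sum(axis=1).argmax()]

    order = np.argsort(-iq, kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    return ICASSOResult(
        run_components=all_comps,
        cluster_assignment=remap[labels],
        iq=iq[order],
        centrotypes=all_comps[centro_idx[order]],
        n_runs=n_runs,
        convergence=np.asarray(conv),
    )


def components_from_icasso(
    result: ICASSOResult, data: np.ndarray, branch: str = "ENL"
) -> ComponentSet:
    """Assemble the final ComponentSet from ICASSO centrotypes: Z-score each
    map across voxels, force the peak-|Z| voxel positive, and compute the
    mixing matrix by least squares against the group data."""
    maps = result.centrotypes.copy()
    z = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, ddof=1, keepdims=True)
    flip = np.sign(z[np.arange(z.shape[0]), np.abs(z).argmax(axis=1)])
    flip[flip == 0] = 1.0
    z *= flip[:, None]
    maps *= flip[:, None]
    mixing = np.linalg.lstsq(z.T, (data - data.mean(axis=1, keepdims=True)).T, rcond=None)[0].T
    return ComponentSet(
        spatial_maps=maps,
        z_maps=z,
        mixing=mixing,
        model_order=maps.shape[0],
        branch=branch,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# classification and matching


def classify_components(
    cs: ComponentSet,
    icasso_result: ICASSOResult,
    gray_matter_mask: np.ndarray,
    iq_threshold: float = 0.80,
    overlap_threshold: float = 0.5,
    z_threshold: float = 1.96,
    labels: Sequence[str | None] | None = None,
) -> NetworkLabelTable:
    """Classify components as networks.

    A component is a network iff (1) its peak-|Z| voxel lies inside the
    gray-matter mask, (2) at least ``overlap_threshold`` of its
    supra-threshold (|Z| > ``z_threshold``) voxels lie inside the mask — an
    automated proxy for visual gray-matter overlap / artifact screening —
    and (3) its ICASSO IQ exceeds ``iq_threshold``.
    """
    mask = np.asarray(gray_matter_mask, dtype=bool).ravel()
    if mask.size != cs.v:
        raise AlignmentError("gray-matter mask length does not match component maps")
    if icasso_result.iq.shape[0] < cs.n_components:
        raise ContractError("missing IQ value for one or more components")
    is_net = np.zeros(cs.n_components, dtype=bool)
    reasons: list[str | None] = []
    for c in range(cs.n_components):
        zmap = cs.z_maps[c]
        peak_in = mask[np.abs(zmap).argmax()]
        supra = np.abs(zmap) > z_threshold
        overlap = mask[supra].mean() if supra.any() else 0.0
        iq = icasso_result.iq[c]
        if not peak_in:
            reasons.append("peak outside gray matter")
        elif overlap < overlap_threshold:
            reasons.append(f"gray-matter overlap {overlap:.2f} < {overlap_threshold}")
        elif iq <= iq_threshold:
            reasons.append(f"IQ <= {iq_threshold:.2f}")
        else:
            reasons.append(None)
            is_net[c] = True
    lab = list(labels) if labels is not None else [None] * cs.n_components
    return NetworkLabelTable(is_network=is_net, labels=lab, rejection_reason=reasons)


def greedy_match_networks(
    enl: ComponentSet,
    lin: ComponentSet,
    enl_table: NetworkLabelTable,
    lin_table: NetworkLabelTable,
    threshold: float = 0.70,
    use_z_maps: bool = True,
) -> MatchTable:
    """Greedy one-to-one matching of ENL and LIN networks on |spatial r|.

    Repeatedly pairs the globally highest remaining absolute spatial
    correlation; ties resolve to the lowest (ENL index, LIN index). A pair
    is concordant iff |r| > ``threshold`` and the two labels are identical.
    Sub-threshold or unmatched networks are listed as unique to their
    branch.
    """
    ei = enl_table.network_indices()
    li = lin_table.network_indices()
    if ei.size == 0 or li.size == 0:
        warnings.warn("empty network set: all components reported as unique")
        return MatchTable(pairs=[], concordant=[], unique_enl=list(ei), unique_lin=list(li))
    me = (enl.z_maps if use_z_maps else enl.spatial_maps)[ei]
    ml = (lin.z_maps if use_z_maps else lin.spatial_maps)[li]
    ze = (me - me.mean(axis=1, keepdims=True)) / np.linalg.norm(
        me - me.mean(axis=1, keepdims=True), axis=1, keepdims=True
    )
    zl = (ml - ml.mean(axis=1, keepdims=True)) / np.linalg.norm(
        ml - ml.mean(axis=1, keepdims=True), axis=1, keepdims=True
    )
    C = np.abs(ze @ zl.T)

    pairs: list[tuple[int, int, float]] = []
    concordant: list[bool] = []
    avail_e = list(range(ei.size))
    avail_l = list(range(li.size))
    while avail_e and avail_l:
        best = (-1.0, None, None)
        for a in avail_e:
            for b in avail_l:
                r = C[a, b]
                if r > best[0] + 1e-15:  # strict improvement; ties keep lowest indices
                    best = (r, a, b)
        r, a, b = best
        pairs.append((int(ei[a]), int(li[b]), float(r)))
        same_label = enl_table.labels[ei[a]] == lin_table.labels[li[b]]
        concordant.append(bool(r > threshold and same_label))
        avail_e.remove(a)
        avail_l.remove(b)

    matched_e = {p[0] for p, c in zip(pairs, concordant) if c}
    matched_l = {p[1] for p, c in zip(pairs, concordant) if c}
    return MatchTable(
        pairs=pairs,
        concordant=concordant,
        unique_enl=[int(i) for i in ei if i not in matched_e],
        unique_lin=[int(i) for i in li if i not in matched_l],
    )


# ---------------------------------------------------------------------------
# GIG-ICA back-reconstruction


def _negentropy(s: np.ndarray) -> float:
    """log-cosh negentropy approximation of a unit-variance source."""
    # E[G(nu)] for standard normal nu, G = log cosh: ~0.3745672
    return float((np.mean(np.log(np.cosh(s))) - 0.37456723) ** 2)


def gig_backreconstruct(
    group: ComponentSet,
    scan_basis: PCABasis | np.ndarray,
    scan_id: str = "",
    similarity_weight: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> ParticipantMapStack:
    """Group-information-guided ICA for one scan.

    For each group network the participant-level source is sought in the
    scan's reduced subspace, maximizing a convex combination of the log-cosh
    negentropy (non-Gaussianity) and the correlation with the group
    reference, starting from the projection of the reference onto the
    subspace. If the ascent diverges the projection initializer is returned
    with a fallback flag.
    """
    if isinstance(scan_basis, PCABasis):
        scores = scan_basis.scores
    else:
        scores = np.asarray(scan_basis, dtype=np.float64)
    v = scores.shape[0]
    if group.v != v:
        raise AlignmentError("group maps and scan data have mismatched voxel dimension")
    # orthonormal basis of the scan subspace (columns), voxel-centered
    Q, _ = np.linalg.qr(scores - scores.mean(axis=0))
    lam = float(similarity_weight)

    k = group.n_components
    maps = np.empty((k, v))
    sims = np.empty(k)
    fellback = np.zeros(k, dtype=bool)
    for c in range(k):
        ref = group.z_maps[c]
        ref = (ref - ref.mean()) / ref.std(ddof=0)
        w = Q.T @ ref
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            w = np.ones(Q.shape[1])
            nrm = np.linalg.norm(w)
        w = w / nrm

        def standardized(wv: np.ndarray) -> np.ndarray:
            s = Q @ wv
            sd = s.std(ddof=0)
            return s / sd if sd > 0 else s

        def objective(wv: np.ndarray) -> float:
            s = standardized(wv)
            rho = float(np.dot(s, ref)) / v
            return (1 - lam) * _negentropy(s) + lam * abs(rho)

        s0 = standardized(w)
        proj_w = w.copy()
        obj = objective(w)
        step = 0.1
        diverged = False
        for _ in range(max_iter):
            s = standardized(w)
            gs = np.tanh(s)
            eg = float(np.mean(np.log(np.cosh(s))) - 0.37456723)
            rho = float(np.dot(s, ref)) / v
            grad_s = (1 - lam) * 2.0 * eg * gs / v + lam * np.sign(rho) * ref / v
            grad = Q.T @ grad_s
            grad -= w * float(np.dot(grad, w))  # tangent to unit sphere
            gn = float(np.linalg.norm(grad))
            if gn < tol:
                break
            w_new = w + step * grad / gn
            w_new /= np.linalg.norm(w_new)
            obj_new = objective(w_new)
            if not np.isfinite(obj_new):
                diverged = True
                break
            if obj_new > obj:
                w, obj = w_new, obj_new
                step = min(step * 1.2, 1.0)
            else:
                step *= 0.5
                if step < 1e-10:
                    break
        if diverged:
            warnings.warn(f"GIG-ICA diverged for component {c}; using projection initializer")
            w = proj_w
            fellback[c] = True
        s = standardized(w)
        if np.dot(s, s0) < 0:  # keep reference orientation
            s = -s
        maps[c] = s
        sims[c] = abs(float(np.dot(s, ref)) / v)

    return ParticipantMapStack(
        maps=maps[None, :, :],
        scan_ids=[scan_id],
        branch=group.branch,
        similarity=sims[None, :],
        fallback=fellback[None, :],
    )


def stack_participant_maps(stacks: Sequence[ParticipantMapStack]) -> ParticipantMapStack:
    """Concatenate single-scan stacks along the scan axis."""
    if not stacks:
        raise ParameterError("no stacks to concatenate")
    return ParticipantMapStack(
        maps=np.concatenate([s.maps for s in stacks], axis=0),
        scan_ids=[sid for s in stacks for sid in s.scan_ids],
        branch=stacks[0].branch,
        similarity=np.concatenate([s.similarity for s in stacks], axis=0)
        if stacks[0].similarity is not None
        else None,
        fallback=np.concatenate([s.fallback for s in stacks], axis=0)
        if stacks[0].fallback is not None
        else None,
    )
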