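"""Synthetic longitudinal infant cohort with planted network couplings.

This module is the ground-truth generator that makes the whole pipeline
testable without restricted data. It emulates the acquisition design of a
longitudinal infant resting-state study — up to three scans per participant
at corrected ages between 0 and 287 days, 410 timepoints per scan — and
plants spatially structured networks whose voxel coupling is *linear*,
*purely nonlinear*, or *mixed*, with age-dependent coupling strength.

Signal model for one scan at corrected age a:

    signal(t, voxel) = sum_k w_k(a) * g_k(s_k(t)) * footprint_k(voxel) + eps

where s_k are independent standard-normal latent sources and eps is white
Gaussian noise. For linear coupling g_k is the identity. For purely
nonlinear coupling the network's voxels form a hub-and-leaves star: a small
hub carries the raw source s and the leaves carry +/-(s^2-1)/sqrt(2), the
parabola channel that is a deterministic function of s yet exactly
uncorrelated with it — so hub-leaf pairs are dependent with zero Pearson
correlation, leaf-leaf pairs are plain (anti)correlated linear pairs, and
the network as a whole exists for distance correlation but never forms a
coherent linear-FC block. Mixed coupling overlays two structures on one
footprint: a shared linear channel with age-flat amplitude (so both
branches see a stable, concordant network) and a hub-and-leaves star on a
second source whose amplitude grows with age (so only the explicitly
nonlinear dependence develops). w_k(a) follows a flat, linear, sigmoidal or
quadratic trajectory in corrected age a.

All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning, so metadata, each scan, and each module-level test can draw
independent, reproducible streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "NetworkSpec",
    "CohortConfig",
    "GroundTruth",
    "default_networks",
    "build_mask",
    "simulate_cohort_metadata",
    "network_footprints",
    "coupling_trajectory",
    "nonlinear_transform",
    "simulate_scan_timeseries",
    "simulate_cohort",
    "export_fixture",
]

Coupling = Literal["linear", "nonlinear", "mixed"]
Trajectory = Literal["flat", "linear", "sigmoid", "quadratic"]


@dataclass
class NetworkSpec:
    """One planted network: spherical Gaussian footprint + coupling law.

    ``center`` is in voxel grid coordinates; ``radius`` in voxels controls
    the footprint extent. ``amplitude`` is the trajectory's scale; the
    sigmoid midpoint/rate are in days.
    """

    name: str
    coupling: Coupling = "linear"
    trajectory: Trajectory = "flat"
    center: tuple[int, int, int] = (4, 4, 2)
    radius: float = 2.0
    amplitude: float = 1.0
    baseline: float = 0.6
    slope: float = 0.0035  # per day, for linear trajectories
    midpoint: float = 100.0  # days, for sigmoid trajectories
    rate: float = 20.0  # days, sigmoid steepness
    curvature: float = -2.5e-5  # per day^2, for quadratic trajectories
    # mixed coupling only: amplitude of the age-coupled nonlinear (star)
    # channel, b(a) = nl_base + nl_amp * sigmoid(a; midpoint, rate), riding
    # on top of the age-flat shared linear channel of strength `baseline`
    nl_base: float = 0.3
    nl_amp: float = 0.0
    # plateau footprints (super-Gaussian) keep the coupling weight nearly
    # uniform across the network's core, so per-voxel amplitude effects
    # (e.g. the mixed network's linear-channel compensation) hold for every
    # analyzed voxel rather than only a representative one
    plateau: bool = False


def default_networks() -> list[NetworkSpec]:
    """Five planted networks covering the coupling x trajectory design:
    three linear, one purely nonlinear (sigmoidal growth with midpoint at
    100 days), one mixed."""
    return [
        NetworkSpec("lin-flat", "linear", "flat", center=(2, 2, 2), radius=1.2, baseline=1.0),
        NetworkSpec("lin-growth", "linear", "linear", center=(7, 2, 2), radius=1.2, baseline=0.5),
        NetworkSpec("lin-sigmoid", "linear", "sigmoid", center=(2, 7, 2), radius=1.2, baseline=0.3),
        NetworkSpec("nl-sigmoid", "nonlinear", "sigmoid", center=(7, 7, 2), radius=1.2, baseline=0.9, amplitude=2.4),
        NetworkSpec(
            "mixed-flat", "mixed", "flat", center=(4, 5, 3), radius=1.2, baseline=1.0,
            nl_base=0.35, nl_amp=0.0,
        ),
    ]


def sensitivity_cohort_networks() -> list[NetworkSpec]:
    """Two-network design for the ENL-vs-LIN developmental sensitivity
    comparison: a concordant linear anchor plus one large concordant mixed
    network whose nonlinear (star) coupling grows sigmoidally with age
    while its linear coupling stays age-flat — development only the ENL
    branch can see."""
    return [
        NetworkSpec("anchor-lin", "linear", "flat", center=(2, 3, 2), radius=1.3, baseline=1.0),
        NetworkSpec(
            "mixed-nlgrowth", "mixed", "flat", center=(6, 6, 2), radius=1.8, baseline=0.8,
            nl_base=0.3, nl_amp=1.4,
        ),
    ]


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the acquisition the pipeline targets: 410 timepoints
    per scan, corrected ages spanning 0-287 days, one to three scans per
    participant, and a desk-scale brain of ~200 in-mask voxels so the full
    pipeline runs in minutes.
    """

    n_participants: int = 30
    max_scans_per_participant: int = 3
    age_range: tuple[float, float] = (0.0, 287.0)
    n_timepoints: int = 410
    grid_shape: tuple[int, int, int] = (10, 10, 5)
    mask_voxels: int = 200
    networks: list[NetworkSpec] = field(default_factory=default_networks)
    noise_sd: float = 1.0
    sex_effect: float = 0.05  # multiplicative coupling modulation, male vs female
    scanner_effect: float = 0.05  # scanner B vs A
    motion_effect: float = 0.3  # per mm mean FD above cohort typical
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 4:
            raise ParameterError("n_timepoints must be >= 4")
        if not (1 <= self.max_scans_per_participant <= 3):
            raise ParameterError("scans per participant must be 1-3")
        if self.age_range[1] <= self.age_range[0]:
            raise ParameterError("empty age range")
        if self.mask_voxels > int(np.prod(self.grid_shape)):
            raise ParameterError("mask larger than grid")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must rediscover."""

    mask: np.ndarray  # 3-D boolean grid
    voxel_index: np.ndarray  # v x 3 grid coordinates, x-fastest order
    footprints: np.ndarray  # networks x v spatial maps
    network_names: list[str]
    coupling_types: list[str]
    trajectories: list[str]
    coupling_by_scan: np.ndarray | None = None  # scans x networks, w_k(age) after modulation


def build_mask(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal 'brain' mask trimmed to exactly ``cfg.mask_voxels``
    voxels (discarding the voxels farthest from center), plus the v x 3
    coordinate table in ascending linear-index (x-fastest) order."""
    nx, ny, nz = cfg.grid_shape
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    c = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
    d2 = ((xs - c[0]) / nx) ** 2 + ((ys - c[1]) / ny) ** 2 + ((zs - c[2]) / nz) ** 2
    flat_order = np.argsort(d2.ravel(order="F"), kind="stable")[: cfg.mask_voxels]
    mask = np.zeros(nx * ny * nz, dtype=bool)
    mask[flat_order] = True
    mask3d = mask.reshape(cfg.grid_shape, order="F")
    lin = np.flatnonzero(mask)  # already ascending, x-fastest
    coords = np.column_stack(np.unravel_index(lin, cfg.grid_shape, order="F"))
    return mask3d, coords


def network_footprints(cfg: CohortConfig, coords: np.ndarray) -> np.ndarray:
    """Gaussian spatial footprints (networks x v), peak 1 at the center."""
    maps = np.empty((len(cfg.networks), coords.shape[0]))
    for k, net in enumerate(cfg.networks):
        d2 = np.sum((coords - np.asarray(net.center)) ** 2, axis=1)
        u = d2 / net.radius**2
        fp = np.exp(-0.5 * u**3) if net.plateau else np.exp(-0.5 * u)
        fp[fp < 0.05] = 0.0  # compact support
        maps[k] = fp
    return maps


def coupling_trajectory(net: NetworkSpec, age: np.ndarray | float) -> np.ndarray | float:
    """Coupling strength w(age) for one network, never negative."""
    age = np.asarray(age, dtype=np.float64)
    if net.trajectory == "flat":
        w = np.full_like(age, net.baseline)
    elif net.trajectory == "linear":
        w = net.baseline + net.slope * age
    elif net.trajectory == "sigmoid":
        w = net.baseline + net.amplitude / (1.0 + np.exp(-(age - net.midpoint) / net.rate))
    elif net.trajectory == "quadratic":
        w = net.baseline + net.amplitude + net.curvature * (age - net.midpoint) ** 2
    else:  # pragma: no cover
        raise ParameterError(f"unknown trajectory {net.trajectory!r}")
    return np.maximum(w, 0.0)


def nonlinear_transform(s: np.ndarray) -> np.ndarray:
    """Zero-Pearson nonlinear channel: (s^2 - 1)/sqrt(2) for standard-normal
    s (zero mean, unit variance, exactly uncorrelated with s)."""
    return (s**2 - 1.0) / np.sqrt(2.0)


def hermite_channels(s: np.ndarray) -> np.ndarray:
    """Star-coupling channels of a standard-normal source: the hub channel
    s and the two signed parabola channels +/-(s^2-1)/sqrt(2). The parabola
    is uncorrelated with s (zero Pearson) yet a deterministic function of
    it, so every hub-leaf voxel pair is dependent without linear
    correlation — coupling a linear FC analysis cannot see. The alternating
    leaf signs keep the leaf group from forming one coherent linear block,
    while distance correlation, being sign-blind, sees the unsigned leaf
    footprint."""
    h2 = (s**2 - 1.0) / np.sqrt(2.0)
    return np.stack([s, h2, -h2])


def simulate_cohort_metadata(cfg: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Longitudinal scan table: repeated participant IDs, ages spread over
    the configured range, per-participant sex, per-scan scanner, and
    right-skewed mean framewise displacement."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    lo, hi = cfg.age_range
    rows = []
    for p in range(cfg.n_participants):
        pid = f"P{p:03d}"
        sex = "F" if rng.random() < 0.5 else "M"
        n_scans = int(rng.integers(1, cfg.max_scans_per_participant + 1))
        ages = np.sort(rng.uniform(lo, hi, size=n_scans))
        for a in ages:
            rows.append(
                dict(
                    participant_id=pid,
                    corrected_age=float(a),
                    sex=sex,
                    scanner="A" if rng.random() < 0.5 else "B",
                    mean_fd=float(rng.gamma(shape=2.0, scale=0.05)),
                )
            )
    meta = pd.DataFrame(rows)
    meta.insert(0, "scan_id", [f"scan{idx:04d}" for idx in range(len(meta))])
    return meta


def _star_amplitude(net: NetworkSpec, age: float) -> float:
    """Mixed coupling's nonlinear (star) channel amplitude b(age)."""
    b = net.nl_base + net.nl_amp / (1.0 + np.exp(-(age - net.midpoint) / net.rate))
    return float(max(b, 0.0))


def _modulated_coupling(cfg: CohortConfig, net: NetworkSpec, row: pd.Series) -> float:
    w = float(coupling_trajectory(net, float(row["corrected_age"])))
    mod = 1.0
    mod += cfg.sex_effect * (1.0 if row["sex"] == "M" else 0.0)
    mod += cfg.scanner_effect * (1.0 if row["scanner"] == "B" else 0.0)
    mod -= cfg.motion_effect * max(float(row["mean_fd"]) - 0.10, 0.0)
    return max(w * mod, 0.0)


def simulate_scan_timeseries(
    cfg: CohortConfig,
    meta_row: pd.Series,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw (not yet Z-scored) timepoints x voxels array for one scan."""
    n, v = cfg.n_timepoints, truth.footprints.shape[1]
    signal = np.zeros((n, v))
    for k, net in enumerate(cfg.networks):
        w = _modulated_coupling(cfg, net, meta_row)
        s = rng.standard_normal(n)
        fp = truth.footprints[k]
        if net.coupling == "linear":
            signal += w * np.outer(s, fp)
        elif net.coupling == "nonlinear":
            # hub-and-leaves star: hub voxels carry the raw source s, leaf
            # voxels carry the signed parabola channels. Every hub-leaf
            # pair is dependent with zero Pearson correlation, so the
            # network exists for distance correlation but not for LIN FC.
            H = hermite_channels(s)
            chan = _channel_assignment(fp)
            for c in range(H.shape[0]):
                sel = chan == c
                if sel.any():
                    signal[:, sel] += w * np.outer(H[c], fp[sel])
        elif net.coupling == "mixed":
            # one shared linear channel (keeps the network visible and
            # stable for Pearson FC in both branches) plus an age-growing
            # hub-and-leaves star on a second source (explicitly nonlinear
            # dependence only). Because voxel time series are Z-scored, a
            # growing star would otherwise dilute the linear correlations
            # with age; the linear amplitude is rescaled by
            # sqrt(1 + b^2 fp_bar^2 / sigma^2) (fp_bar^2 = mean squared
            # footprint over the support) so the Pearson block stays
            # age-flat while only the ENL coupling develops.
            b = _star_amplitude(net, float(meta_row["corrected_age"]))
            # energy-weighted representative footprint: the compensation is
            # exact for the high-footprint voxels that pass the |Z| test
            # threshold and get analyzed downstream
            sup = fp[fp > 0]
            fpbar2 = float(np.sum(sup**4) / np.sum(sup**2))
            a_lin = w * np.sqrt(1.0 + b * b * fpbar2 / max(cfg.noise_sd**2, 1e-12))
            signal += a_lin * np.outer(s, fp)
            s2 = rng.standard_normal(n)
            H = hermite_channels(s2)
            chan = _channel_assignment(fp)
            for c in range(H.shape[0]):
                sel = chan == c
                if sel.any():
                    signal[:, sel] += b * np.outer(H[c], fp[sel])
        else:  # pragma: no cover
            raise ParameterError(f"unknown coupling {net.coupling!r}")
    signal += cfg.noise_sd * rng.standard_normal((n, v))
    return signal


#: repeating deal of star channels over a footprint's voxels: an eighth of
#: voxels form the hub (channel 0, the raw source), the rest split evenly
#: between the +parabola and -parabola leaf channels, interleaved by
#: footprint weight so hub and leaves each span the whole spatial extent
_STAR_DEAL = (0, 1, 2, 1, 1, 2, 1, 2)


def _channel_assignment(footprint: np.ndarray, deal: tuple = _STAR_DEAL) -> np.ndarray:
    """Hermite channel index per voxel (-1 outside the footprint support),
    dealt in the hub-and-leaves pattern by descending footprint weight."""
    chan = np.full(footprint.size, -1)
    support = np.flatnonzero(footprint > 0)
    order = support[np.argsort(-footprint[support], kind="stable")]
    deal_arr = np.array(deal)
    chan[order] = deal_arr[np.arange(order.size) % len(deal_arr)]
    return chan


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[pd.DataFrame, list[np.ndarray], GroundTruth]:
    """Full cohort: metadata table, one raw scan array per row, and the
    ground truth. Deterministic for a fixed ``cfg.seed``."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    meta_seed, *scan_seeds = ss.spawn(1 + 10000)
    meta = simulate_cohort_metadata(cfg, np.random.default_rng(meta_seed))
    mask3d, coords = build_mask(cfg)
    footprints = network_footprints(cfg, coords)
    truth = GroundTruth(
        mask=mask3d,
        voxel_index=coords,
        footprints=footprints,
        network_names=[n.name for n in cfg.networks],
        coupling_types=[n.coupling for n in cfg.networks],
        trajectories=[n.trajectory for n in cfg.networks],
    )
    scans = []
    coupling = np.zeros((len(meta), len(cfg.networks)))
    for i, (_, row) in enumerate(meta.iterrows()):
        rng = np.random.default_rng(scan_seeds[i])
        scans.append(simulate_scan_timeseries(cfg, row, truth, rng))
        coupling[i] = [_modulated_coupling(cfg, net, row) for net in cfg.networks]
    truth.coupling_by_scan = coupling
    return meta, scans, truth


def export_fixture(cfg: CohortConfig, out_dir: str | Path) -> dict:
    """Write a round-trippable fixture: 4-D NIfTI per scan, the 3-D mask,
    the metadata CSV, and a compressed ground-truth archive (kept separate
    from the pipeline inputs). Returns the path manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta, scans, truth = simulate_cohort(cfg)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(truth.mask.astype(np.uint8), affine), out / "mask.nii")
    scan_paths = []
    for sid, raw in zip(meta["scan_id"], scans):
        vol = np.zeros((*cfg.grid_shape, cfg.n_timepoints), dtype=np.float32)
        vol[truth.mask, :] = raw.T.astype(np.float32)
        p = out / f"{sid}.nii"
        nib.save(nib.Nifti1Image(vol, affine), p)
        scan_paths.append(str(p))
    meta.to_csv(out / "metadata.csv", index=False)
    np.savez_compressed(
        out / "ground_truth.npz",
        footprints=truth.footprints,
        voxel_index=truth.voxel_index,
        coupling_by_scan=truth.coupling_by_scan,
        network_names=np.asarray(truth.network_names),
        coupling_types=np.asarray(truth.coupling_types),
        trajectories=np.asarray(truth.trajectories),
    )
    manifest = {
        "mask": str(out / "mask.nii"),
        "metadata": str(out / "metadata.csv"),
        "ground_truth": str(out / "ground_truth.npz"),
        "scans": scan_paths,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "networks": [asdict(n) for n in cfg.networks]},
    }
    return manifest
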