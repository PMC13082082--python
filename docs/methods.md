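# Methods

`enlfc` estimates the *explicitly nonlinear* (ENL) part of functional
connectivity: the statistical dependence between two voxel time series that
exceeds what a bivariate Gaussian with the same linear correlation would
produce. This note records the models, the numeric choices, and what the
synthetic cohort does and does not emulate.

## ENL functional connectivity

For Z-scored voxel series x, y of length n:

* **LIN** — Pearson correlation, computed as r = (1/(n−1)) Σ xᵢyᵢ on the
  normalized columns.
* **NL** — the squared bias-corrected distance correlation R²ₙ (the
  U-statistic estimator built from U-centered Euclidean distance matrices,
  with the 1/(n(n−3)) inner product), truncated at zero and square-rooted.
  The U-statistic is mean-zero under independence, so small-sample bias does
  not masquerade as dependence; truncation plus square root puts it on the
  distance-correlation scale.
* **NULL** — the distance correlation a *bivariate Gaussian* pair with the
  observed r would have:

      dCor²_Gauss(r) = (r·asin r + √(1−r²) − r·asin(r/2) − √(4−r²) + 1)
                       / (1 + π/3 − √3)

  The closed form is the *squared* distance correlation, so its square root
  is taken to match NL's scale. This choice is verified numerically: the
  square-rooted form agrees with the empirical sqrt-truncated estimator on
  large bivariate-normal samples to <0.01 at n=10⁵; the unrooted form does
  not. The function is even in r, monotone in |r|, 0 at r=0, 1 at |r|=1;
  inputs a hair outside [−1,1] (≤1e−12) are clamped before asin.
* **ENL = NL − NULL**, diagonal forced to 0, *not* truncated: only R²ₙ is
  truncated, and sampling noise legitimately makes ENL slightly negative.

Whole-brain matrices flatten each voxel's U-centered matrix once and take
blockwise Gram products (block size configurable, default 64 voxels), so
the all-pairs computation is a handful of matrix multiplications. Single
pairs at large n (>4000) go through a numba kernel that streams over pairs
in O(n) memory using the algebraic identity
Σ_{i≠j} AᵢⱼBᵢⱼ = [ab] − 2/(n−2)·Σ rᵢsᵢ + g_a g_b/((n−1)(n−2)) on raw
distance row sums; it reproduces the matrix path to 1e−10.

Zero-variance voxels are rejected at normalization with the voxel index
named, never silently masked.

## Connectivity-domain group ICA

Each scan's FC matrix is treated as v observations (voxels) × v features
(connectivity profiles): scan-level PCA keeps 30 components, scans are
concatenated along the feature axis, group PCA keeps 20, and Infomax ICA
unmixes the 20×v group data into spatial maps. Infomax uses full-batch
natural-gradient updates with the logistic nonlinearity, learning rate 0.1
annealed ×0.9 on update-direction oscillation, tolerance 1e−6, max 1000
iterations. (The tiny per-sample learning rates familiar from GIFT do not
converge in a full-batch setting; with these defaults planted Laplace
sources are recovered at |r| > 0.99.)

Stability: ICASSO with 100 runs by default (random initialization +
voxel-resampling bootstrap; the unmixing learned on the resample is applied
to the original data so run components stay comparable), average-linkage
clustering on 1 − |Pearson| between maps, cut at the model order.
IQ = mean intra-cluster − mean extra-cluster similarity; centrotype = the
member maximizing within-cluster similarity. Clusters are reported in
descending IQ order.

A component is a network iff its peak-|Z| voxel lies in gray matter, at
least half of its |Z|>1.96 voxels lie in gray matter (an automated proxy
for visual inspection), and IQ > .80. Branch matching is greedy on
|spatial correlation| of Z-maps with ties broken toward the lowest index
pair; a pair is concordant iff |r| > .70 and labels agree.

GIG-ICA back-reconstruction seeks, per scan and group network, a source in
the scan's reduced subspace maximizing (1−λ)·(log-cosh negentropy)² +
λ·|corr with the reference| (λ = 0.5), by projected gradient ascent on the
unit sphere initialized from the reference's projection; divergence falls
back to the projection with a flag. On planted perturbations the
reconstructed maps sit closer to the participant truth than the group
reference does.

## Developmental trajectory model

Per voxel: weight ~ f(age) + sex + scanner + mean FD + (1 | participant).
The smooth f is a rank-reduced 1-D thin-plate regression spline (radial
basis |Δage|³ on unit-scaled age, eigen-truncated to basis dimension 10,
side conditions absorbed; penalty null space = straight lines). The random
intercept is a ridge-penalized block of participant indicators. Both
smoothing parameters are selected on a log-spaced grid by a Laplace
marginal-likelihood (ML) score; REML is available, but ML guards noticeably
better against spurious wiggliness under a linear truth (on matched
simulations, EDF<1.5 under a linear ground truth in ~95% of fits for ML vs
~83% for REML — mgcv reproduces both numbers), and the basis matters: the
thin-plate construction is what achieves this, while B-spline/CR bases
hover near 85% under either criterion. EDF of the age smooth (sum of the
hat-diagonal over its columns) is the trajectory-complexity measure: ~1
linear, ≥3 highly nonlinear.

The smooth is tested with an approximate Wald F statistic on its
coefficient block (Bayesian covariance, numerator df = EDF, denominator
df = n − total EDF). Its calibration is not assumed but measured: at the
default study scale (72 participants, ~130 scans) the null false-positive
rate at α=.05 sits at 0.05–0.07 over thousands of fits. Because the design
matrix depends only on scan metadata, one model object is built per network
and reused across voxels; per-voxel work is a few Cholesky solves per grid
point. BH-FDR is applied across each network's tested (|Z|>1.96) voxels.

Branch comparisons: EDF values of significant voxels are compared by
two-sided independent permutation tests (5000 permutations, add-one p) with
Hedges's g (J = 1 − 3/(4·df − 1); paired designs standardize by the SD of
differences); voxel significance patterns are compared by two-sided
McNemar tests (continuity-corrected χ² = (|b−c|−1)²/(b+c), exact binomial p
when b+c < 25, OR = ENL-only/LIN-only so OR > 1 is an ENL advantage), with
Bonferroni at .05/15 (14 concordant pairs + 1 overall).

## Synthetic cohort

The generator emulates the target acquisition: 410 timepoints per scan,
corrected ages 0–287 days, 1–3 scans per participant, sex and scanner
covariates, right-skewed mean framewise displacement, and ~200 in-mask
voxels on a small 3-D grid so the full pipeline runs in minutes. Voxel
signal is a sum of network drives weighted by Gaussian spatial footprints
and age-dependent coupling trajectories (flat/linear/sigmoid/quadratic;
the sigmoid midpoint defaults to 100 days), plus white Gaussian noise.
Covariates modulate coupling multiplicatively (sex +5%, scanner +5%,
motion −30%/mm above typical FD).

Coupling types:

* **linear** — all footprint voxels share the source s.
* **nonlinear** — a hub-and-leaves star: one voxel in eight carries s, the
  rest carry ±(s²−1)/√2, the parabola channel that is a deterministic
  function of s yet exactly uncorrelated with it. Every hub–leaf pair is
  dependent with zero Pearson correlation; leaf–leaf pairs are ordinary
  (anti)correlated linear pairs. Because distance correlation is blind to
  sign, the ENL matrix contains one homogeneous hub×leaf block whose leaf
  side is the *unsigned* footprint — a single stable ICA component —
  whereas linear FC sees only sign-split sub-blocks that never match the
  full map. This construction was chosen after quantitative comparison:
  shared-drive transforms, per-scan channel re-deals, variance
  (volatility) coupling, block-sign mixtures, and harmonic-stack designs
  all fail either on distance-correlation strength at n=410 or on
  ICA stability.
* **mixed** — a shared linear channel plus a star on a second source. In
  the dedicated two-network *sensitivity* cohort the star amplitude grows
  sigmoidally with age: the network is concordant between branches, but
  only its explicitly nonlinear coupling develops — the configuration used
  to demonstrate the ENL branch's greater developmental sensitivity.
  Because voxel series are Z-scored, a growing star would dilute the
  linear correlations with age, so the linear channel's amplitude is
  rescaled by √(1 + b²·f̄p²/σ²) with f̄p² the energy-weighted mean squared
  footprint — the compensation is then exact for the high-footprint voxels
  that pass the |Z| test threshold, keeping the Pearson block age-flat
  where it is analyzed. Notably, simply mixing s and (s²−1)/√2 into one
  shared drive does *not* create ENL signal: a shared non-Gaussian drive
  plus independent noise yields a linear pair whose distance correlation
  sits at or below the Gaussian null.

All randomness flows from one master seed through `SeedSequence` spawning
(one stream for metadata, one per scan), so every artifact is reproducible
bit-for-bit.

What the generator does **not** emulate: hemodynamics and temporal
autocorrelation (sources are white), motion artifacts beyond a scalar FD
covariate, scanner-specific noise spectra, and spatial autocorrelation of
noise. Passing tests therefore demonstrate the estimators' statistical
behavior and the pipeline's recovery properties under the stated couplings,
not performance on real infant fMRI.

## Problem sizes and determinism

The test suite and the acceptance script run the planted-network analyses
at 16 participants (~30 scans) with 16 ICASSO runs, and the GAM
calibration at 72 participants (~130–150 scans) with 200 recovery fits and
2000 null fits; the library defaults stay at the study parameters (100
runs, model order 20, PCA 30/20). The developmental-sensitivity comparison
pools the four-outcome voxel tallies over three replicate sensitivity
cohorts (45 participants each) before the single overall McNemar test:
each cohort's discordant count (~10 ENL-only : 0 LIN-only) sits near the
resolution limit of the exact binomial at the Bonferroni level, and
pooling independent replicates is the sufficient-statistic way to measure
the same odds ratio with adequate power. Estimator checks use n=10⁵ samples for
the Gaussian-null agreement (streaming kernel), n=5000 for ENL nullity, and
1000 replicate pairs at n=50 for unbiasedness. Every stochastic stage takes
an explicit seed; pipelines derive stage seeds from the master seed by
stream splitting.

## Known limitations

* Distance correlation at n≈400 resolves only fairly strong zero-Pearson
  dependence (the parabola motif); subtler nonlinear couplings need longer
  series.
* The GAM smooth test is approximate; its mild anticonservatism at small
  cohort sizes (FPR up to ~0.08 at ~60 scans) shrinks at study scale.
* Greedy matching is one-to-one and label-aware; split components (two
  components covering one network) count as unique, not partial matches.
* The McNemar odds ratio is reported with a +0.5 Haldane correction in the
  acceptance summary when a branch has zero exclusive voxels.
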