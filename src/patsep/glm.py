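"""Trial-wise response estimation (least-squares-single) and multivariate
noise normalization.

Each trial gets its own GLM: the trial-of-interest is one HRF-convolved
regressor, all other trials collapse into a second regressor, plus optional
nuisance columns and polynomial drift up to degree 2. The trial t-statistic
(beta vs. the implicit baseline, i.e. beta / SE(beta)) is the pattern value
carried into all multivariate analyses. Residuals pooled across trial-GLMs
feed a shrinkage covariance estimate used to whiten patterns by the inverse
symmetric square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .synthdata import BoldRun, PatternSet, TrialSequence


def hrf_kernel(
    tr: float,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    peak_disp: float = 1.0,
    under_delay: float = 16.0,
    under_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    dt: float | None = None,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr`` (or ``dt``), unit peak.

    Difference of two gamma densities; with the defaults the kernel peaks
    close to 5 s after stimulus onset and shows a late undershoot.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    step = dt if dt is not None else tr

    def shape(t):
        return (gamma_dist.pdf(t, peak_delay, scale=peak_disp)
                - ratio * gamma_dist.pdf(t, under_delay, scale=under_disp))

    # unit-peak normalization against the continuous-time peak, so coarse
    # sampling is an exact subsample of the fine-grid kernel
    peak = shape(np.arange(0.0, duration_s, 0.001)).max()
    return shape(np.arange(0.0, duration_s, step)) / peak


@dataclass
class TrialEstimates:
    betas: np.ndarray      # (n_trials, n_voxels)
    tstats: np.ndarray     # (n_trials, n_voxels)
    residuals: np.ndarray  # (n_trials * n_timepoints, n_voxels), pooled
    dof: int               # residual dof of each trial-GLM


def _drift_columns(n_t: int, degree: int = 2) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n_t)
    cols = [np.ones(n_t)]
    for d in range(1, degree + 1):
        c = x**d
        c = c - c.mean()  # orthogonal to the intercept
        cols.append(c)
    return np.stack(cols, axis=1)


def fit_lss(
    bold_run: BoldRun,
    trial_sequence: TrialSequence | None = None,
    nuisance: np.ndarray | None = None,
    hrf: np.ndarray | None = None,
    drop_initial: int = 0,
    drift_degree: int | None = 2,
) -> TrialEstimates:
    """Least-squares-single estimation of every trial's response.

    ``drop_initial`` volumes are removed before fitting (saturation guard).
    ``drift_degree`` adds intercept + polynomial drift columns up to that
    degree; ``None`` fits without drift columns (for data with a true zero
    baseline, where LSS is exactly the one-shot GLM when trials do not
    overlap). Raises on rank-deficient designs, naming the offending trial.
    """
    data = bold_run.data  # (n_vox, n_t)
    tr = bold_run.tr
    onsets = bold_run.onsets
    n_vox, n_t = data.shape
    if hrf is None:
        hrf = hrf_kernel(tr)

    sticks = np.zeros((onsets.size, n_t))
    for i, on in enumerate(onsets):
        sticks[i, int(round(on / tr))] = 1.0
    convolved = np.array([np.convolve(s, hrf)[:n_t] for s in sticks])

    keep = slice(drop_initial, n_t)
    Y = data.T[keep]  # (n_t_kept, n_vox)
    convolved = convolved[:, keep]
    n_kept = Y.shape[0]
    drift = (np.empty((n_kept, 0)) if drift_degree is None
             else _drift_columns(n_kept, drift_degree))
    nuis = np.empty((n_kept, 0)) if nuisance is None else np.asarray(nuisance)[keep]

    all_zero = not np.any(Y)
    betas = np.zeros((onsets.size, n_vox))
    tstats = np.zeros((onsets.size, n_vox))
    resids = []
    for i in range(onsets.size):
        others = convolved.sum(axis=0) - convolved[i]
        X = np.column_stack([convolved[i], others, nuis, drift])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design for trial {i} (rank {rank} < {X.shape[1]})")
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y
        R = Y - X @ B
        dof = n_kept - X.shape[1]
        sigma2 = (R**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[0, 0])
        betas[i] = B[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstats[i] = np.where(se > 0, B[0] / se, np.nan)
        resids.append(R)
    estimates = TrialEstimates(
        betas=betas,
        tstats=tstats,
        residuals=np.concatenate(resids, axis=0),
        dof=n_kept - (2 + nuis.shape[1] + drift.shape[1]),
    )
    if all_zero:
        estimates.tstats[:] = np.nan  # flagged: t undefined on all-zero data
    return estimates


@dataclass
class NoiseCovariance:
    matrix: np.ndarray   # (n_vox, n_vox), symmetric positive definite
    shrinkage: float     # in [0, 1]


def estimate_noise_covariance(residuals: np.ndarray,
                              shrinkage: float | str = "auto") -> NoiseCovariance:
    """Sample covariance of GLM residuals shrunk toward its diagonal.

    ``shrinkage='auto'`` picks the Schafer-Strimmer analytic intensity for the
    diagonal target (off-diagonal correlations scaled by 1 - lambda); a float
    in [0, 1] fixes the intensity. The result is symmetric positive definite
    as long as every voxel has positive variance.
    """
    R = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("residuals contain non-finite values")
    n, p = R.shape
    if n <= 2:
        shrinkage = 1.0
    Rc = R - R.mean(axis=0, keepdims=True)
    S = Rc.T @ Rc / (n - 1 if n > 1 else 1)
    d = np.sqrt(np.clip(np.diag(S), 1e-300, None))
    corr = S / np.outer(d, d)

    if shrinkage == "auto":
        X = Rc / d  # standardized
        w_bar = corr * (n - 1) / n
        # var_hat(r_ij) via the w_kij = x_ki x_kj moments
        sq = (X**2).T @ (X**2)  # sum_k w_kij^2
        var_r = n / (n - 1) ** 3 * (sq - n * w_bar**2)
        off = ~np.eye(p, dtype=bool)
        denom = np.sum(corr[off] ** 2)
        lam = 1.0 if denom <= 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")

    corr_shrunk = (1.0 - lam) * corr
    np.fill_diagonal(corr_shrunk, 1.0)
    cov = corr_shrunk * np.outer(d, d)
    cov = (cov + cov.T) / 2.0
    return NoiseCovariance(matrix=cov, shrinkage=lam)


def noise_normalize(patterns: PatternSet, noise_cov: NoiseCovariance) -> PatternSet:
    """Whiten patterns by the inverse symmetric square root of the covariance."""
    C = noise_cov.matrix
    if C.shape[0] != patterns.n_voxels:
        raise ValueError(
            f"covariance is {C.shape[0]}x{C.shape[0]} but patterns have "
            f"{patterns.n_voxels} voxels")
    vals, vecs = np.linalg.eigh(C)
    if vals.min() <= 0:
        raise ValueError("covariance is not positive definite")
    W = vecs @ np.diag(vals**-0.5) @ vecs.T
    return PatternSet(
        data=patterns.data @ W,
        stim_ids=list(patterns.stim_ids),
        roi=patterns.roi,
        condition=patterns.condition,
        group=patterns.group,
    )
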