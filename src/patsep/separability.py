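"""Cosine-angle pattern separability and circular-statistical inference.

Separability between two stimuli is the angle between their (whitened)
voxel-pattern vectors, theta = arccos(cos-similarity), in degrees within
[0, 180]. Angle sets are compared with circular statistics: the
Watson-Williams F test for independent samples, a paired Hotelling test on
(cos, sin) differences for matched samples, and a confidence-interval test of
the circular mean against a reference direction. Population response
magnitude (per-stimulus L2 norm of un-normalized t patterns) and its
decoupling from separability (Spearman across ROI x condition cells) live
here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import PatternSet


@dataclass
class AngleSet:
    angles: np.ndarray                # degrees in [0, 180]
    pair_labels: list[tuple[str, str]]
    roi: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return self.angles.size


@dataclass
class CircularTestResult:
    statistic: float
    df: tuple[int, int]
    p_raw: float
    p_adj: float | None = None
    warning: str | None = None


def pairwise_angles(pattern_set: PatternSet) -> AngleSet:
    """All n(n-1)/2 pairwise angles between stimulus patterns, degrees."""
    X = pattern_set.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm pattern for stimulus {pattern_set.stim_ids[zero[0]]!r}")
    cosmat = (X @ X.T) / np.outer(norms, norms)
    iu, ju = np.triu_indices(X.shape[0], k=1)
    theta = np.degrees(np.arccos(np.clip(cosmat[iu, ju], -1.0, 1.0)))
    labels = [(pattern_set.stim_ids[i], pattern_set.stim_ids[j]) for i, j in zip(iu, ju)]
    return AngleSet(angles=theta, pair_labels=labels,
                    roi=pattern_set.roi, condition=pattern_set.condition)


# -- circular helpers -------------------------------------------------------

def _resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """(mean direction deg, resultant length r) of angles treated as directions."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    C, S = np.cos(rad).sum(), np.sin(rad).sum()
    R = np.hypot(C, S)
    mean = np.degrees(np.arctan2(S, C)) % 360.0
    return mean, float(R / rad.size)


def circular_mean_angle(angle_set: AngleSet | np.ndarray) -> float:
    """Direction of the resultant of unit vectors at the given angles (deg)."""
    angles = angle_set.angles if isinstance(angle_set, AngleSet) else np.asarray(angle_set)
    if angles.size == 0:
        raise ValueError("empty angle set")
    mean, r = _resultant(angles)
    if r < 1e-12:
        raise ValueError("zero resultant: circular mean undefined")
    return mean


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood-ish von Mises concentration from resultant length."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(angles_a: np.ndarray, angles_b: np.ndarray) -> CircularTestResult:
    """Watson-Williams F test for a common mean direction of two samples.

    F = K (N-2)(R1+R2-R) / (N-R1-R2) with df (1, N-2); K = 1 + 3/(8 kappa) is
    the standard concentration correction. A validity warning is set when the
    pooled within-sample resultant length falls below 0.45.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    n1, n2 = a.size, b.size
    N = n1 + n2
    _, r1 = _resultant(a)
    _, r2 = _resultant(b)
    _, r = _resultant(np.concatenate([a, b]))
    R1, R2, R = n1 * r1, n2 * r2, N * r
    rw = (R1 + R2) / N
    kappa = _kappa_from_r(rw)
    K = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = N - (R1 + R2)
    if denom <= 0:
        F = 0.0 if abs(R1 + R2 - R) < 1e-12 else np.inf
    else:
        F = K * (N - 2) * (R1 + R2 - R) / denom
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, N - 2))
    warn = "low concentration (rw < 0.45): Watson-Williams may be invalid" if rw < 0.45 else None
    return CircularTestResult(statistic=float(F), df=(1, N - 2), p_raw=p, warning=warn)


def hotelling_paired(angles_a: np.ndarray, angles_b: np.ndarray) -> CircularTestResult:
    """Paired Hotelling test for equal angular means of matched samples.

    Pair differences are taken on the unit circle, d_i = (cos a_i - cos b_i,
    sin a_i - sin b_i); a one-sample Hotelling T2 against (0, 0) gives
    F = (n-2)/(2(n-1)) T2 with df (2, n-2).
    """
    a = np.radians(np.asarray(angles_a, dtype=float))
    b = np.radians(np.asarray(angles_b, dtype=float))
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    D = np.stack([np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)], axis=1)
    dbar = D.mean(axis=0)
    S = np.cov(D, rowvar=False)
    if np.allclose(S, 0):
        F = 0.0 if np.allclose(dbar, 0) else np.inf
    else:
        T2 = n * dbar @ np.linalg.pinv(S) @ dbar
        F = (n - 2) / (2 * (n - 1)) * T2
    p = float(stats.f.sf(F, 2, n - 2))
    return CircularTestResult(statistic=float(F), df=(2, n - 2), p_raw=p)


def one_sample_mean_angle_test(
    angle_set: AngleSet | np.ndarray, mu0: float, alpha: float = 0.05
) -> CircularTestResult:
    """Test whether ``mu0`` lies outside the (1-alpha) CI of the circular mean.

    The CI half-width follows the standard circular-mean confidence arc
    (chi-square construction). ``statistic`` is the angular deviation of the
    sample mean from mu0 in units of the CI half-width, so values > 1 are
    significant at alpha.
    """
    angles = angle_set.angles if isinstance(angle_set, AngleSet) else np.asarray(angle_set)
    n = angles.size
    if n == 0:
        raise ValueError("empty angle set")
    mean, r = _resultant(angles)
    if r < 1e-12:
        raise ValueError("undefined circular mean")
    R = n * r
    chi2 = stats.chi2.ppf(1 - alpha, 1)
    if r >= 0.9:
        t = np.sqrt(n**2 - (n**2 - R**2) * np.exp(chi2 / n))
    elif r > np.sqrt(chi2 / (2 * n)):
        t = np.sqrt((2 * n * (2 * R**2 - n * chi2)) / (4 * n - chi2))
    else:
        return CircularTestResult(statistic=np.nan, df=(1, n - 1), p_raw=1.0,
                                  warning="sample too dispersed for a mean-angle CI")
    half_width = np.degrees(np.arccos(np.clip(t / R, -1.0, 1.0)))
    dev = abs((mean - mu0 + 180.0) % 360.0 - 180.0)
    stat = dev / half_width if half_width > 0 else np.inf
    p = alpha if stat > 1 else 1.0  # CI-based decision, not a continuous p
    return CircularTestResult(statistic=float(stat), df=(1, n - 1), p_raw=float(p))


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


# -- magnitude --------------------------------------------------------------

@dataclass
class MagnitudeSet:
    norms: np.ndarray
    stim_ids: list[str] = field(default_factory=list)
    roi: str = ""
    condition: str = ""

    @property
    def mean_norm(self) -> float:
        return float(self.norms.mean())


def population_magnitude(pattern_set: PatternSet) -> MagnitudeSet:
    """Per-stimulus L2 norm across voxels of the un-normalized t patterns."""
    return MagnitudeSet(
        norms=np.linalg.norm(pattern_set.data, axis=1),
        stim_ids=list(pattern_set.stim_ids),
        roi=pattern_set.roi,
        condition=pattern_set.condition,
    )


def magnitude_separability_decoupling(mean_angles_by_cell, mean_norms_by_cell):
    """Spearman rank correlation between mean angles and mean norms across
    analysis cells (e.g. 3 ROIs x 3 conditions -> df = 7). Returns (rho, df, p)."""
    a = np.asarray(mean_angles_by_cell, dtype=float)
    m = np.asarray(mean_norms_by_cell, dtype=float)
    if a.size != m.size:
        raise ValueError("cell vectors must have equal length")
    if a.size < 4:
        raise ValueError("need at least 4 cells")
    rho, p = stats.spearmanr(a, m)
    return float(rho), int(a.size - 2), float(p)
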