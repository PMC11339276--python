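"""Participation-ratio dimensionality with permutation noise ceilings.

PR = (sum lambda)^2 / sum lambda^2 over the eigenvalues of the
stimulus-by-stimulus covariance of (trial-averaged, whitened) patterns, so the
estimate is bounded by the number of stimuli. Noise ceilings come from
synchronized permutations: each voxel's values are independently shuffled
across stimuli, destroying cross-voxel stimulus structure while preserving
marginals. Condition/ROI contrasts compare the observed PR difference with the
permutation distribution of differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_for
from .synthdata import PatternSet


@dataclass
class PRResult:
    pr: float
    eigenvalues: np.ndarray
    noise_ceiling: np.ndarray | None = None   # permuted PRs
    p_vs_ceiling: float | None = None         # one-sided: observed below ceiling
    roi: str = ""
    condition: str = ""
    comparisons: dict = field(default_factory=dict)


def pr_from_eigenvalues(eigenvalues: np.ndarray) -> float:
    lam = np.asarray(eigenvalues, dtype=float)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        raise ValueError("zero covariance: participation ratio undefined")
    return float(s**2 / np.square(lam).sum())


def _stimulus_eigenvalues(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    C = Xc @ Xc.T / max(X.shape[0] - 1, 1)
    return np.clip(np.linalg.eigvalsh(C), 0.0, None)


def participation_ratio(pattern_set: PatternSet) -> PRResult:
    """PR of the stimulus covariance (patterns centered across stimuli)."""
    X = pattern_set.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    lam = _stimulus_eigenvalues(X)
    if lam.sum() <= 0:
        raise ValueError("all-constant patterns: zero covariance")
    return PRResult(pr=pr_from_eigenvalues(lam), eigenvalues=lam,
                    roi=pattern_set.roi, condition=pattern_set.condition)


def _permuted_prs(X: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    n, v = X.shape
    out = np.empty(n_perm)
    for k in range(n_perm):
        perm = np.argsort(rng.random((v, n)), axis=1)  # independent shuffle per voxel
        Xp = X[perm.T, np.arange(v)[None, :]]
        out[k] = pr_from_eigenvalues(_stimulus_eigenvalues(Xp))
    return out


def pr_noise_ceiling(pattern_set: PatternSet, n_perm: int = 1000, seed: int = 0) -> PRResult:
    """PR plus its permutation noise ceiling.

    One-sided p = (#{permuted PR <= observed} + 1) / (n_perm + 1) for the
    "dimensionality is lower than the ceiling" test (add-one corrected).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    res = participation_ratio(pattern_set)
    rng = rng_for(seed, "pr_ceiling", pattern_set.roi, pattern_set.condition)
    ceil = _permuted_prs(pattern_set.data, n_perm, rng)
    res.noise_ceiling = ceil
    res.p_vs_ceiling = float((np.sum(ceil <= res.pr) + 1) / (n_perm + 1))
    return res


def compare_pr(
    patterns_a: PatternSet,
    patterns_b: PatternSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided test of the PR difference (a - b) against the noise
    distribution of synchronized-permutation PR differences.

    Both sets are permuted (independent within-voxel shuffles) per draw; the
    observed difference is referenced to the centered distribution of
    permuted-PR differences, i.e. the difference must exceed what the two
    noise ceilings' variability allows. Returns (difference, p).
    """
    if patterns_a.n_stimuli != patterns_b.n_stimuli:
        raise ValueError("pattern sets must have the same stimulus count")
    obs = participation_ratio(patterns_a).pr - participation_ratio(patterns_b).pr
    rng = rng_for(seed, "pr_compare", patterns_a.roi, patterns_a.condition,
                  patterns_b.roi, patterns_b.condition)
    diffs = (_permuted_prs(patterns_a.data, n_perm, rng)
             - _permuted_prs(patterns_b.data, n_perm, rng))
    p = float((np.sum(np.abs(diffs) >= abs(obs)) + 1) / (n_perm + 1))
    return float(obs), p
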