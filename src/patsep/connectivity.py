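"""Pattern connectivity between face areas.

Shared representational structure between areas is quantified as the
repeated-measures correlation (rmcorr) of 1st-level RDM cells across area
pairs: observations are lower-triangle RDM cells, the grouping factor is the
area pair, and both RDMs are first residualized on the rank-transformed
low-level (Gabor) control RDM. The expected-vs-context-free contrast is a
stimulus-level bootstrap of the rmcorr difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._rng import rng_for
from .rsa import RDM, _rank


@dataclass
class ConnectivityResult:
    rm_rho: float
    df: int
    p: float
    condition: str = ""
    n_pairs: int = 0
    n_cells: int = 0


def _residualize_on(v: np.ndarray, control: np.ndarray | None) -> np.ndarray:
    rv = _rank(v)
    if control is None:
        return rv - rv.mean()
    rc = _rank(control)
    A = np.column_stack([np.ones_like(rc), rc])
    return rv - A @ np.linalg.lstsq(A, rv, rcond=None)[0]


def rm_correlation(x: np.ndarray, y: np.ndarray, groups: np.ndarray) -> tuple[float, int, float]:
    """Repeated-measures correlation: within-group centering, pooled Pearson,
    df = N - k - 1. Returns (r, df, p). With a single group this reduces to
    the ordinary correlation (df = N - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    xc, yc = x.copy(), y.copy()
    uniq = np.unique(groups)
    for g in uniq:
        m = groups == g
        xc[m] -= xc[m].mean()
        yc[m] -= yc[m].mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise ValueError("zero variance after within-group centering")
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    df = x.size - uniq.size - 1
    if df <= 0:
        raise ValueError("not enough observations for rmcorr")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return r, df, p


def _pairwise_cells(rdms_by_area: dict[str, RDM], control_rdm: RDM | None):
    areas = sorted(rdms_by_area)
    if len(areas) < 2:
        raise ValueError("need at least two areas")
    labels = rdms_by_area[areas[0]].labels
    for a in areas:
        if rdms_by_area[a].labels != labels:
            raise ValueError(f"RDM labels for area {a!r} do not match")
    if control_rdm is not None and control_rdm.labels != labels:
        raise ValueError("control RDM labels do not match")
    ctrl = control_rdm.vector() if control_rdm is not None else None
    xs, ys, gs = [], [], []
    for gi, (a, b) in enumerate(combinations(areas, 2)):
        xs.append(_residualize_on(rdms_by_area[a].vector(), ctrl))
        ys.append(_residualize_on(rdms_by_area[b].vector(), ctrl))
        gs.append(np.full(xs[-1].size, gi))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs), len(list(combinations(areas, 2)))


def pattern_connectivity(
    rdms_by_area: dict[str, RDM],
    control_rdm: RDM | None = None,
    condition: str = "",
) -> ConnectivityResult:
    """rmcorr of RDM cells across all area pairs, controlling for the
    low-level RDM by rank residualization."""
    x, y, g, n_pairs = _pairwise_cells(rdms_by_area, control_rdm)
    r, df, p = rm_correlation(x, y, g)
    n_cells = x.size // n_pairs
    return ConnectivityResult(rm_rho=r, df=df, p=p, condition=condition,
                              n_pairs=n_pairs, n_cells=n_cells)


def _rm_from_resampled(rdms_by_area, control_rdm, idx):
    areas = sorted(rdms_by_area)
    iu, ju = np.triu_indices(idx.size, k=1)
    keep = idx[iu] != idx[ju]
    ctrl = None
    if control_rdm is not None:
        ctrl = control_rdm.matrix[np.ix_(idx, idx)][iu, ju][keep]
    xs, ys, gs = [], [], []
    for gi, (a, b) in enumerate(combinations(areas, 2)):
        va = rdms_by_area[a].matrix[np.ix_(idx, idx)][iu, ju][keep]
        vb = rdms_by_area[b].matrix[np.ix_(idx, idx)][iu, ju][keep]
        xs.append(_residualize_on(va, ctrl))
        ys.append(_residualize_on(vb, ctrl))
        gs.append(np.full(va.size, gi))
    r, _, _ = rm_correlation(np.concatenate(xs), np.concatenate(ys), np.concatenate(gs))
    return r


def connectivity_condition_contrast(
    rdms_a: dict[str, RDM],
    rdms_b: dict[str, RDM],
    control_a: RDM | None = None,
    control_b: RDM | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stimulus-level bootstrap of the rmcorr difference (condition a - b).

    The two conditions may involve different stimulus sets (each with its own
    low-level control RDM); the bootstrap resamples face indices jointly for
    both conditions. One-sided: p is the add-one fraction of bootstrap
    differences <= 0, testing whether connectivity is higher in condition a.
    Returns (observed difference, p).
    """
    if sorted(rdms_a) != sorted(rdms_b):
        raise ValueError("conditions must cover the same area set")
    obs = (pattern_connectivity(rdms_a, control_a).rm_rho
           - pattern_connectivity(rdms_b, control_b).rm_rho)
    n = rdms_a[sorted(rdms_a)[0]].n
    if rdms_b[sorted(rdms_b)[0]].n != n:
        raise ValueError("conditions must have the same stimulus count")
    rng = rng_for(seed, "connectivity_contrast")
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.unique(idx).size < 3:
            idx = rng.integers(0, n, size=n)
        try:
            diffs[k] = (_rm_from_resampled(rdms_a, control_a, idx)
                        - _rm_from_resampled(rdms_b, control_b, idx))
        except ValueError:
            diffs[k] = 0.0
    p = float((np.sum(diffs < 0) + 0.5 * np.sum(diffs == 0) + 1) / (n_boot + 1))
    return float(obs), p
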