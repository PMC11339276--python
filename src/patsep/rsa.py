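"""Representational similarity analysis and prediction-error geometry.

1st-level RDMs are cosine-distance matrices over whitened voxel patterns.
Model RDMs encode the classical tuning accounts of the face-processing
hierarchy: view-specific shape (Spearman distances between landmark vectors),
appearance (Spearman distances between view-bearing appearance vectors),
view-invariant appearance (distances between the identities' frontal
appearance vectors regardless of the displayed view), and mirror symmetry (a
binary RDM that is 0 within a view and between left/right profiles). A Gabor
wavelet pyramid over the stimulus images provides the low-level control that
is partialled out of the 2nd-level fits.

2nd-level inference: partial Spearman correlation of the 1st-level RDM with
each model RDM controlling for the Gabor RDM, Fisher z, stimulus-level
bootstrap; best-model comparisons by bootstrap, condition contrasts of
dependent non-overlapping correlations by the Raghunathan-Rosenthal-Rubin
test, and independent-sample contrasts by Fisher's z test.

Prediction-error (PE) geometry: matched differences unexpected - expected on
whitened t patterns, then a cosine-distance RDM over the difference patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from ._rng import rng_for
from .synthdata import PatternSet, StimulusSet

MODELS = ("shape", "mirror_symmetry", "appearance", "view_invariant_appearance")


@dataclass
class RDM:
    matrix: np.ndarray
    labels: list[str]
    metric: str = "cosine"          # cosine | spearman_distance | binary
    level: str = "first"            # first | model | pe

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("RDM must be square")
        if M.shape[0] < 3:
            raise ValueError("RDM needs at least 3 stimuli")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(M), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        self.matrix = (M + M.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


def first_level_rdm(pattern_set: PatternSet) -> RDM:
    """Cosine-distance RDM (1 - cos similarity) over whitened patterns."""
    X = pattern_set.data
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm pattern for stimulus {pattern_set.stim_ids[zero[0]]!r}")
    D = 1.0 - (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(D, 0.0)
    return RDM(matrix=(D + D.T) / 2, labels=list(pattern_set.stim_ids), metric="cosine")


def _spearman_distance_rdm(features: np.ndarray, labels: list[str]) -> RDM:
    F = np.asarray(features, dtype=float)
    if np.any(np.ptp(F, axis=1) == 0):
        bad = int(np.flatnonzero(np.ptp(F, axis=1) == 0)[0])
        raise ValueError(f"constant feature vector (undefined ranks) for {labels[bad]!r}")
    ranks = np.apply_along_axis(stats.rankdata, 1, F)
    Rc = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Rc, axis=1)
    corr = (Rc @ Rc.T) / np.outer(denom, denom)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return RDM(matrix=D, labels=labels, metric="spearman_distance", level="model")


def model_rdm_shape(stimuli: StimulusSet) -> RDM:
    """Spearman distances between landmark-position vectors."""
    return _spearman_distance_rdm(stimuli.landmarks, list(stimuli.table["stim_id"]))


def model_rdm_appearance(stimuli: StimulusSet) -> RDM:
    """Spearman distances between (view-bearing) appearance vectors."""
    return _spearman_distance_rdm(stimuli.appearance, list(stimuli.table["stim_id"]))


def model_rdm_view_invariant_appearance(stimuli: StimulusSet, full_set: StimulusSet) -> RDM:
    """Distances between the identities' frontal (canonical) appearance
    vectors, assigned to every view combination of the identity pair."""
    idents = stimuli.table["identity"].to_numpy()
    frontal = np.array([full_set.canonical_appearance(int(i)) for i in idents])
    base = _spearman_distance_rdm(frontal, list(stimuli.table["stim_id"]))
    M = base.matrix.copy()
    # same identity in different views: distance 0 by construction of ranks
    same = idents[:, None] == idents[None, :]
    M[same] = 0.0
    return RDM(matrix=M, labels=base.labels, metric="spearman_distance", level="model")


def model_rdm_mirror_symmetry(view_labels: list[str], stim_labels: list[str] | None = None) -> RDM:
    """Binary RDM: 0 within a view and between left/right profiles; 1 otherwise."""
    allowed = {"frontal", "left_profile", "right_profile"}
    unknown = set(view_labels) - allowed
    if unknown:
        raise ValueError(f"unknown view labels: {sorted(unknown)}")
    collapsed = ["profile" if v != "frontal" else v for v in view_labels]
    c = np.array(collapsed)
    M = (c[:, None] != c[None, :]).astype(float)
    np.fill_diagonal(M, 0.0)
    labels = stim_labels if stim_labels is not None else list(view_labels)
    return RDM(matrix=M, labels=list(labels), metric="binary", level="model")


# -- Gabor wavelet pyramid control ------------------------------------------

def gabor_features(
    images: np.ndarray,
    n_scales: int = 4,
    n_orientations: int = 8,
    pool_grid: int = 4,
    min_frequency: float = 0.08,
) -> np.ndarray:
    """Multi-scale, multi-orientation Gabor energy pooled on a spatial grid."""
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim != 3:
        raise ValueError("images must be (n, H, W)")
    H, W = imgs.shape[1:]
    freqs = min_frequency * 2.0 ** np.arange(n_scales)
    kernels = [gabor_kernel(frequency=f, theta=np.pi * o / n_orientations)
               for f in freqs for o in range(n_orientations)]
    edges_r = np.linspace(0, H, pool_grid + 1).astype(int)
    edges_c = np.linspace(0, W, pool_grid + 1).astype(int)
    feats = []
    for img in imgs:
        per = []
        for k in kernels:
            resp = fftconvolve(img - img.mean(), np.real(k), mode="same") \
                + 1j * fftconvolve(img - img.mean(), np.imag(k), mode="same")
            energy = np.abs(resp)
            pooled = [energy[edges_r[i]:edges_r[i + 1], edges_c[j]:edges_c[j + 1]].mean()
                      for i in range(pool_grid) for j in range(pool_grid)]
            per.extend(pooled)
        feats.append(per)
    return np.array(feats)


def gabor_control_rdm(stimuli: StimulusSet, **kwargs) -> RDM:
    """Spearman-distance RDM over Gabor pyramid features of the images."""
    sizes = {im.shape for im in stimuli.images}
    if len(sizes) != 1:
        raise ValueError("images must share one size")
    F = gabor_features(stimuli.images, **kwargs)
    return _spearman_distance_rdm(F, list(stimuli.table["stim_id"]))


# -- 2nd level ---------------------------------------------------------------

@dataclass
class ModelFit:
    rho: float
    z: float
    bootstrap_z: np.ndarray


@dataclass
class ModelFitSet:
    fits: dict[str, ModelFit]
    intercorrelations: np.ndarray   # (1 + n_models [+control]) square, Spearman
    intercorr_labels: list[str] = field(default_factory=list)
    n_stimuli: int = 0


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def _partial_spearman(x: np.ndarray, y: np.ndarray, control: np.ndarray | None) -> float:
    """Spearman correlation of x and y, partialling ``control`` (on ranks)."""
    rx, ry = _rank(x), _rank(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("degenerate (constant) RDM vector")
    if control is not None:
        rc = _rank(control)
        A = np.column_stack([np.ones_like(rc), rc])
        rx = rx - A @ np.linalg.lstsq(A, rx, rcond=None)[0]
        ry = ry - A @ np.linalg.lstsq(A, ry, rcond=None)[0]
    else:
        rx, ry = rx - rx.mean(), ry - ry.mean()
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def _tri_vector_resampled(M: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = M[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(idx.size, k=1)
    keep = idx[iu] != idx[ju]  # drop cells pairing a stimulus with itself
    return sub[iu, ju][keep]


def second_level_fit(
    first_rdm: RDM,
    model_rdms: dict[str, RDM],
    control_rdm: RDM | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> ModelFitSet:
    """Partial Spearman fit of each model RDM to the 1st-level RDM.

    The bootstrap resamples stimuli (rows and columns jointly) with
    replacement, respecting the dependence among RDM cells that share a
    stimulus; Fisher z is stored per draw.
    """
    labels = first_rdm.labels
    for name, m in model_rdms.items():
        if m.labels != labels:
            raise ValueError(f"model {name!r} labels do not match the 1st-level RDM")
    if control_rdm is not None and control_rdm.labels != labels:
        raise ValueError("control RDM labels do not match")

    v1 = first_rdm.vector()
    ctrl = control_rdm.vector() if control_rdm is not None else None
    n = first_rdm.n
    rng = rng_for(seed, "second_level")

    fits = {}
    boot_idx = [rng.integers(0, n, size=n) for _ in range(n_boot)]
    # reject degenerate draws with < 3 distinct stimuli
    boot_idx = [ix if np.unique(ix).size >= 3 else np.arange(n) for ix in boot_idx]
    for name, m in model_rdms.items():
        rho = _partial_spearman(v1, m.vector(), ctrl)
        bz = np.empty(n_boot)
        for k, ix in enumerate(boot_idx):
            bv1 = _tri_vector_resampled(first_rdm.matrix, ix)
            bvm = _tri_vector_resampled(m.matrix, ix)
            bc = _tri_vector_resampled(control_rdm.matrix, ix) if control_rdm is not None else None
            try:
                r = _partial_spearman(bv1, bvm, bc)
            except ValueError:
                r = 0.0
            bz[k] = np.arctanh(np.clip(r, -0.999999, 0.999999))
        fits[name] = ModelFit(rho=rho, z=float(np.arctanh(np.clip(rho, -0.999999, 0.999999))),
                              bootstrap_z=bz)

    names = ["first"] + list(model_rdms)
    vecs = [v1] + [m.vector() for m in model_rdms.values()]
    if ctrl is not None:
        names.append("control")
        vecs.append(ctrl)
    k = len(vecs)
    inter = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter[i, j] = inter[j, i] = stats.spearmanr(vecs[i], vecs[j]).statistic
    return ModelFitSet(fits=fits, intercorrelations=inter, intercorr_labels=names,
                       n_stimuli=n)


def best_model_test(fit_set: ModelFitSet, candidate: str) -> tuple[float, float]:
    """One-sided bootstrap test: candidate z exceeds the mean of the others.

    Returns (observed difference, p) with p = add-one fraction of bootstrap
    differences <= 0.
    """
    if candidate not in fit_set.fits:
        raise KeyError(candidate)
    others = [n for n in fit_set.fits if n != candidate]
    if not others:
        raise ValueError("need at least two fitted models")
    obs = fit_set.fits[candidate].z - np.mean([fit_set.fits[n].z for n in others])
    bdiff = fit_set.fits[candidate].bootstrap_z \
        - np.mean([fit_set.fits[n].bootstrap_z for n in others], axis=0)
    n_boot = bdiff.size
    # ties (exactly equal fits) count half, so identical models sit near 0.5
    p = float((np.sum(bdiff < 0) + 0.5 * np.sum(bdiff == 0) + 1) / (n_boot + 1))
    return float(obs), p


def raghunathan_test(r_jk: float, r_hm: float, intercorrelations: dict, n: int,
                     alternative: str = "greater") -> tuple[float, float]:
    """Raghunathan-Rosenthal-Rubin test for dependent, non-overlapping
    correlations r_jk vs r_hm measured on the same n observations.

    ``intercorrelations`` must supply r_jh, r_jm, r_kh, r_km (the four
    cross-correlations linking the two pairs). The statistic is
    z = (z_jk - z_hm) sqrt((n-3) / (2 - 2c)) with c the Pearson-Filon
    covariance of the two correlations scaled by their variances.
    ``alternative``: 'greater' tests r_jk > r_hm, 'less' the reverse,
    'two-sided' both. Returns (z, p).
    """
    for r in (r_jk, r_hm):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 10:
        raise ValueError("n must be >= 10")
    r_jh = intercorrelations["r_jh"]
    r_jm = intercorrelations["r_jm"]
    r_kh = intercorrelations["r_kh"]
    r_km = intercorrelations["r_km"]
    k = (0.5 * r_jk * r_hm * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
         + r_jh * r_km + r_jm * r_kh
         - (r_jk * r_jh * r_jm + r_jk * r_kh * r_km
            + r_hm * r_jh * r_kh + r_hm * r_jm * r_km))
    c = k / ((1 - r_jk**2) * (1 - r_hm**2))
    c = float(np.clip(c, -0.999999, 0.999999))
    z = (np.arctanh(r_jk) - np.arctanh(r_hm)) * np.sqrt((n - 3) / (2 - 2 * c))
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be greater, less, or two-sided")
    return float(z), p


def fisher_independent_test(r1: float, n1: int, r2: float, n2: int,
                            alternative: str = "greater") -> tuple[float, float]:
    """Fisher z test for independent, non-overlapping correlations."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if min(n1, n2) <= 3:
        raise ValueError("samples must have n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be greater, less, or two-sided")
    return float(z), p


# -- prediction-error geometry ----------------------------------------------

@dataclass
class PEPatternSet:
    data: np.ndarray          # (n_matched, n_voxels) difference patterns
    stim_ids: list[str]       # matched (expected) stimulus ids
    violation_type: str       # identity | view
    roi: str = ""


def pe_geometry(
    expected: PatternSet,
    unexpected: PatternSet,
    violation_type: str = "identity",
) -> tuple[PEPatternSet, RDM]:
    """Difference patterns (unexpected - expected, matched stimuli) and their
    cosine-distance RDM. Raises a degenerate-PE error on all-zero differences.
    """
    if violation_type not in ("identity", "view"):
        raise ValueError("violation_type must be 'identity' or 'view'")
    if expected.stim_ids != unexpected.stim_ids:
        raise ValueError("expected and unexpected pattern sets must be stimulus-matched")
    D = unexpected.data - expected.data
    norms = np.linalg.norm(D, axis=1)
    if np.any(norms == 0):
        bad = expected.stim_ids[int(np.flatnonzero(norms == 0)[0])]
        raise ValueError(f"degenerate PE: zero difference pattern for {bad!r}")
    pes = PEPatternSet(data=D, stim_ids=list(expected.stim_ids),
                       violation_type=violation_type, roi=expected.roi)
    rdm = first_level_rdm(PatternSet(data=D, stim_ids=list(expected.stim_ids),
                                     roi=expected.roi, condition=f"pe_{violation_type}"))
    rdm.level = "pe"
    return pes, rdm
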