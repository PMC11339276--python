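"""Synthetic study generator.

Emulates a statistical-learning fMRI experiment on face pairs: a trained set of
18 facial identities x 3 trained views (frontal, left profile, right profile)
split into 9 predictor-successor pairs, a test phase with 60% expected
successors and 40% violations (unexpected identity or unexpected view), per-ROI
voxel patterns with configurable representational geometry (view-specific
shape, mirror-symmetric, appearance, or view-invariant appearance tuning),
BOLD runs built from those patterns, and pupil traces entrained at the 0.5 Hz
pair frequency of a 1 Hz image stream.

Everything is deterministic given its seed, so downstream analyses can be
tested against known ground truth without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import ttest_ind

from ._rng import rng_for

# Seven rendered head orientations; 0 deg is frontal, 300/330 turn left,
# 30/60 turn right. Trained views are frontal and the two 60-deg profiles.
VIEW_ANGLES = {
    "frontal": 0,
    "right_30": 30,
    "right_45": 45,
    "right_profile": 60,
    "left_profile": 300,
    "left_45": 315,
    "left_30": 330,
}
TRAINED_VIEWS = ("frontal", "right_profile", "left_profile")
UNTRAINED_VIEWS = ("right_30", "right_45", "left_45", "left_30")

CONDITIONS = ("context_free_predictor", "expected", "unexpected_identity", "unexpected_view")

INTRA_PAIR_JITTERS = (1.5, 3.5, 5.5)   # seconds, successor baseline
INTER_PAIR_JITTERS = (5.5, 7.5, 9.5)   # seconds, between pairs
STIMULUS_DURATION = 0.5                # seconds


class DesignError(ValueError):
    """An experimental design constraint cannot be satisfied."""


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """Synthetic face stimuli with landmark, appearance, and image features.

    ``table`` has one row per stimulus with columns
    ``stim_id, identity, view, view_angle_deg, role, trained``; feature arrays
    are row-aligned with the table.
    """

    table: pd.DataFrame
    landmarks: np.ndarray    # (n_stim, 2*L) canvas coordinates
    appearance: np.ndarray   # (n_stim, A)
    images: np.ndarray       # (n_stim, H, W) luminance in [0, 1]

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    def index_of(self, stim_id: str) -> int:
        idx = self.table.index[self.table["stim_id"] == stim_id]
        if len(idx) != 1:
            raise KeyError(f"stimulus {stim_id!r} not found")
        return int(idx[0])

    def select(self, stim_ids: list[str]) -> "StimulusSet":
        rows = [self.index_of(s) for s in stim_ids]
        return StimulusSet(
            table=self.table.iloc[rows].reset_index(drop=True),
            landmarks=self.landmarks[rows],
            appearance=self.appearance[rows],
            images=self.images[rows],
        )

    def canonical_appearance(self, identity: int) -> np.ndarray:
        """The identity's frontal-view appearance vector."""
        mask = (self.table["identity"] == identity) & (self.table["view"] == "frontal")
        idx = self.table.index[mask]
        if len(idx) == 0:
            raise DesignError(f"identity {identity} has no frontal stimulus")
        return self.appearance[int(idx[0])]


def _landmark_template(L: int) -> np.ndarray:
    # Fixed face-like scaffold: points on two nested ellipses plus a center line.
    t = np.linspace(0.0, 2 * np.pi, L, endpoint=False)
    x = 0.5 + 0.30 * np.cos(t) * (1.0 + 0.12 * np.sin(3 * t))
    y = 0.5 + 0.38 * np.sin(t) * (1.0 + 0.08 * np.cos(2 * t))
    return np.stack([x, y], axis=1)  # (L, 2)


def _render_image(landmarks: np.ndarray, appearance: np.ndarray, size: int = 32) -> np.ndarray:
    """Deterministic luminance rendering: Gaussian bumps at landmark positions
    with amplitudes cycled from the appearance vector; exact mean 0.5."""
    L = landmarks.size // 2
    pts = landmarks.reshape(L, 2)
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1.0)
    amps = appearance[np.arange(L) % appearance.size]
    sig2 = 2 * 0.05**2
    d2 = (xx[None] - pts[:, 0, None, None]) ** 2 + (yy[None] - pts[:, 1, None, None]) ** 2
    img = np.tensordot(amps, np.exp(-d2 / sig2), axes=1)
    img = img - img.mean()
    peak = np.abs(img).max()
    if peak > 0:
        img = 0.45 * img / peak
    return img + 0.5


def generate_stimulus_set(
    n_identities: int = 18,
    views: tuple[str, ...] = tuple(VIEW_ANGLES),
    L_landmarks: int = 68,
    A_features: int = 50,
    seed: int = 0,
    image_size: int = 32,
) -> StimulusSet:
    """Generate faces as identity x view records.

    Landmarks are identity- and view-dependent (view deformation dominates,
    matching view-specific shape tuning); appearance vectors are
    identity-dominant with an additive view component that is zero for the
    frontal view, so the frontal appearance is the identity's canonical
    appearance. Left- and right-profile renderings of an identity are not
    pixel mirror images (an identity-by-view jitter breaks the symmetry).
    """
    if n_identities % 2:
        raise DesignError("n_identities must be even so identities can be paired")
    unknown = set(views) - set(VIEW_ANGLES)
    if unknown:
        raise DesignError(f"unknown views: {sorted(unknown)}")

    rng = rng_for(seed, "stimuli")
    template = _landmark_template(L_landmarks)

    # View deformation is a smooth function of signed head angle: one field
    # scales with sin(angle) (opposite turns displace landmarks oppositely),
    # one with 1 - cos(angle) (symmetric foreshortening). Frontal is
    # undeformed; left and right profiles are anti-similar in shape space.
    D_turn = rng_for(seed, "view_field", "turn").normal(0.0, 0.11, size=(L_landmarks, 2))
    D_fore = rng_for(seed, "view_field", "foreshorten").normal(0.0, 0.11, size=(L_landmarks, 2))

    def _signed_angle(deg: int) -> float:
        return np.radians(deg if deg <= 180 else deg - 360)

    view_shape = {
        v: D_turn * np.sin(_signed_angle(a)) + D_fore * (1 - np.cos(_signed_angle(a)))
        for v, a in VIEW_ANGLES.items()
    }
    view_app = {
        v: (np.zeros(A_features) if v == "frontal"
            else rng_for(seed, "view_app", v).normal(0.0, 0.6, size=A_features))
        for v in VIEW_ANGLES
    }

    roles = np.array(["predictor"] * (n_identities // 2) + ["successor"] * (n_identities // 2))
    rng.shuffle(roles)

    # Identity features are drawn for predictors and mapped to successors by a
    # random orthogonal rotation: the two role sets then have identical
    # feature-space geometry (Gram spectra), enforcing the role balance the
    # paradigm requires (no separability differences between predictor and
    # successor stimulus sets).
    pred_idx = [i for i in range(n_identities) if roles[i] == "predictor"]
    succ_idx = [i for i in range(n_identities) if roles[i] == "successor"]
    id_shapes = np.empty((n_identities, L_landmarks * 2))
    canonicals = np.empty((n_identities, A_features))
    for i in pred_idx:
        id_shapes[i] = rng.normal(0.0, 0.05, size=L_landmarks * 2)
        canonicals[i] = rng.normal(0.0, 1.0, size=A_features)
    Q_shape, _ = np.linalg.qr(rng.normal(size=(L_landmarks * 2, L_landmarks * 2)))
    Q_app, _ = np.linalg.qr(rng.normal(size=(A_features, A_features)))
    for k, i in enumerate(succ_idx):
        id_shapes[i] = id_shapes[pred_idx[k]] @ Q_shape
        canonicals[i] = canonicals[pred_idx[k]] @ Q_app

    rows, lms, apps, imgs = [], [], [], []
    for ident in range(n_identities):
        id_shape = id_shapes[ident].reshape(L_landmarks, 2)
        canonical = canonicals[ident]
        for view in views:
            angle = VIEW_ANGLES[view]
            # small identity-by-view term: profiles are not exact mirrors
            ixv = rng.normal(0.0, 0.012, size=(L_landmarks, 2))
            pts = template + id_shape + view_shape[view] + ixv
            app = canonical + view_app[view] + rng.normal(0.0, 0.05, size=A_features)
            rows.append({
                "stim_id": f"id{ident:02d}_{view}",
                "identity": ident,
                "view": view,
                "view_angle_deg": angle,
                "role": roles[ident],
                "trained": view in TRAINED_VIEWS,
            })
            lms.append(pts.reshape(-1))
            apps.append(app)
            imgs.append(_render_image(pts.reshape(-1), app, size=image_size))

    return StimulusSet(
        table=pd.DataFrame(rows),
        landmarks=np.array(lms),
        appearance=np.array(apps),
        images=np.array(imgs),
    )


# ---------------------------------------------------------------------------
# Pair design
# ---------------------------------------------------------------------------

@dataclass
class PairDesign:
    """9 predictor-successor pairs plus the recombined violation stimuli."""

    pairs: list[dict]  # keys: predictor, successor, unexpected_identity, unexpected_views

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def predictor_ids(self) -> list[str]:
        return [p["predictor"] for p in self.pairs]

    def successor_ids(self) -> list[str]:
        return [p["successor"] for p in self.pairs]


def build_pairs(stimulus_set: StimulusSet, seed: int = 0) -> PairDesign:
    """Pair predictor and successor identities with balanced head orientations.

    Each identity contributes one trained identity-view image; views are
    balanced (3 per trained view) separately within predictors and successors.
    Unexpected-identity successors are the trained successor images of other
    pairs (a seeded derangement), never novel identities; unexpected views are
    two untrained orientations of the expected successor identity, when the
    stimulus set contains untrained views.
    """
    rng = rng_for(seed, "pairs")
    tab = stimulus_set.table
    trained = tab[tab["trained"]]
    pred_ids = sorted(trained.loc[trained["role"] == "predictor", "identity"].unique())
    succ_ids = sorted(trained.loc[trained["role"] == "successor", "identity"].unique())
    if len(pred_ids) != len(succ_ids):
        raise DesignError("predictor and successor identity counts differ")
    n = len(pred_ids)
    if n % len(TRAINED_VIEWS):
        raise DesignError("identities per role must be divisible by the trained view count")
    for ids in (pred_ids, succ_ids):
        for ident in ids:
            have = set(trained.loc[trained["identity"] == ident, "view"])
            if not set(TRAINED_VIEWS) <= have:
                raise DesignError(f"identity {ident} lacks trained views {set(TRAINED_VIEWS) - have}")

    def balanced_views() -> list[str]:
        v = list(TRAINED_VIEWS) * (n // len(TRAINED_VIEWS))
        rng.shuffle(v)
        return v

    pred_views = balanced_views()
    succ_views = balanced_views()
    pred_ids = list(pred_ids)
    succ_ids = list(succ_ids)
    rng.shuffle(pred_ids)
    rng.shuffle(succ_ids)

    # seeded derangement for identity violations
    shift = int(rng.integers(1, n))
    have_untrained = set(UNTRAINED_VIEWS) & set(tab["view"])

    pairs = []
    for i in range(n):
        succ_ident = succ_ids[i]
        unexpected_views: list[str] = []
        if have_untrained:
            pool = sorted(have_untrained)
            pick = rng.choice(len(pool), size=min(2, len(pool)), replace=False)
            unexpected_views = [f"id{succ_ident:02d}_{pool[j]}" for j in sorted(pick)]
        pairs.append({
            "predictor": f"id{pred_ids[i]:02d}_{pred_views[i]}",
            "successor": f"id{succ_ident:02d}_{succ_views[i]}",
            "unexpected_identity": f"id{succ_ids[(i + shift) % n]:02d}_{succ_views[(i + shift) % n]}",
            "unexpected_views": unexpected_views,
        })
    return PairDesign(pairs=pairs)


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

@dataclass
class TrialSequence:
    """Ordered, timed trial list. ``table`` columns:
    onset (s), stim_id, pair_index, role, condition, baseline_after (s)."""

    table: pd.DataFrame
    phase: str  # "training" | "test"
    tr: float = 2.0

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def pair_onsets(self) -> np.ndarray:
        t = self.table
        return t.loc[t["role"] == "predictor", "onset"].to_numpy()


def generate_training_sequence(pair_design: PairDesign, n_repeats: int = 1, seed: int = 0) -> TrialSequence:
    """Training stream at a 1 Hz image rate (500 ms image, 500 ms blank).

    Within-pair transitional probability is 100% by construction; between-pair
    transitions are balanced greedily (next pair = least-used transition from
    the current pair among those not yet shown in the block).
    """
    if n_repeats < 1:
        raise DesignError("n_repeats must be >= 1")
    rng = rng_for(seed, "training_sequence")
    n = pair_design.n_pairs
    counts = np.zeros((n, n))
    order: list[int] = []
    prev = -1
    for _ in range(n_repeats):
        remaining = set(range(n))
        while remaining:
            if prev < 0:
                nxt = int(rng.choice(sorted(remaining)))
            else:
                cands = sorted(remaining - {prev}) or sorted(remaining)
                cmin = min(counts[prev, c] for c in cands)
                best = [c for c in cands if counts[prev, c] == cmin]
                nxt = int(best[int(rng.integers(len(best)))])
                counts[prev, nxt] += 1
            order.append(nxt)
            remaining.discard(nxt)
            prev = nxt

    rows = []
    t = 0.0
    for k in order:
        pair = pair_design.pairs[k]
        rows.append({"onset": t, "stim_id": pair["predictor"], "pair_index": k,
                     "role": "predictor", "condition": "context_free_predictor",
                     "baseline_after": 0.5})
        rows.append({"onset": t + 1.0, "stim_id": pair["successor"], "pair_index": k,
                     "role": "successor", "condition": "expected",
                     "baseline_after": 0.5})
        t += 2.0
    return TrialSequence(table=pd.DataFrame(rows), phase="training")


def generate_test_sequence(
    pair_design: PairDesign,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    n_trials: int = 90,
    intra_jitters: tuple[float, ...] = INTRA_PAIR_JITTERS,
    inter_jitters: tuple[float, ...] = INTER_PAIR_JITTERS,
    seed: int = 0,
    tr: float = 2.0,
    t0: float = 10.0,
) -> TrialSequence:
    """Test phase: ``n_trials`` pair presentations with exact-count condition
    allocation (expected / unexpected_identity / unexpected_view) and jittered
    baselines; every stimulus onset falls on the TR grid."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise DesignError("proportions must sum to 1")
    counts = [p * n_trials for p in proportions]
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise DesignError(
            f"proportions {proportions} not exactly realizable with {n_trials} trials")
    counts = [int(round(c)) for c in counts]
    if counts[2] > 0 and not pair_design.pairs[0]["unexpected_views"]:
        raise DesignError("view violations requested but the design has no untrained views")

    rng = rng_for(seed, "test_sequence")
    n_pairs = pair_design.n_pairs

    # interleave conditions over pairs as evenly as possible, then shuffle order
    slots: list[tuple[int, str]] = []
    for cond, c in zip(("expected", "unexpected_identity", "unexpected_view"), counts):
        pair_cycle = list(range(n_pairs)) * (c // n_pairs + 1)
        rng.shuffle(pair_cycle)
        slots.extend((pair_cycle[i], cond) for i in range(c))
    rng.shuffle(slots)

    # snap a baseline-generated gap to the TR grid (jitters are chosen so that
    # 0.5 s stimulus + jitter is already a TR multiple when tr == 2)
    rows = []
    t = t0
    view_flip: dict[int, int] = {}
    for pair_idx, cond in slots:
        pair = pair_design.pairs[pair_idx]
        j1 = float(rng.choice(intra_jitters))
        j2 = float(rng.choice(inter_jitters))
        if cond == "expected":
            succ = pair["successor"]
        elif cond == "unexpected_identity":
            succ = pair["unexpected_identity"]
        else:
            flip = view_flip.get(pair_idx, 0)
            succ = pair["unexpected_views"][flip % len(pair["unexpected_views"])]
            view_flip[pair_idx] = flip + 1
        rows.append({"onset": t, "stim_id": pair["predictor"], "pair_index": pair_idx,
                     "role": "predictor", "condition": "context_free_predictor",
                     "baseline_after": j1})
        succ_onset = t + STIMULUS_DURATION + j1
        rows.append({"onset": succ_onset, "stim_id": succ, "pair_index": pair_idx,
                     "role": "successor", "condition": cond, "baseline_after": j2})
        t = succ_onset + STIMULUS_DURATION + j2
    seq = TrialSequence(table=pd.DataFrame(rows), phase="test", tr=tr)
    if tr > 0 and np.max(np.abs(np.mod(seq.table["onset"].to_numpy(), tr))) > 1e-9:
        raise DesignError("onsets do not fall on the TR grid with these jitters")
    return seq


# ---------------------------------------------------------------------------
# ROI patterns with controlled geometry
# ---------------------------------------------------------------------------

TUNING_MODELS = ("shape", "mirror_symmetry", "appearance", "view_invariant_appearance")


@dataclass
class GeometrySpec:
    """Ground-truth geometry for one ROI x condition cell.

    tuning_weights: mixture over the four tuning models (nonnegative, sum 1).
    target_mean_angle: circular mean of pairwise pattern angles in the
        noiseless limit, degrees in (0, 180); realized within +-2 deg.
    extra_context_dims: orthogonal condition-specific components added to the
        stimulus-specific part (raises dimensionality and separability).
    amplitude_gain: overall response magnitude multiplier.
    noise_sd: per-voxel, per-trial noise standard deviation; patterns are the
        average of ``n_trials`` noisy repeats (trial-averaged t-statistics).
    shared_weight: blend weight of an across-ROI shared latent geometry
        (models a common top-down component); requires ``shared_latent``.
    """

    tuning_weights: dict[str, float]
    target_mean_angle: float
    n_voxels: int = 200
    extra_context_dims: int = 0
    amplitude_gain: float = 1.0
    noise_sd: float = 0.0
    n_trials: int = 36
    shared_weight: float = 0.0
    seed: int = 0            # structural stream: projections, context axes
    noise_seed: int | None = None  # measurement stream; defaults to seed

    def __post_init__(self) -> None:
        unknown = set(self.tuning_weights) - set(TUNING_MODELS)
        if unknown:
            raise DesignError(f"unknown tuning models: {sorted(unknown)}")
        w = np.array([self.tuning_weights.get(m, 0.0) for m in TUNING_MODELS])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise DesignError("tuning_weights must be nonnegative and sum to 1")
        if not 0.0 < self.target_mean_angle < 180.0:
            raise DesignError("target_mean_angle must lie in (0, 180) degrees")


@dataclass
class PatternSet:
    """Stimuli x voxels activity patterns for one ROI and condition."""

    data: np.ndarray          # (n_stim, n_voxels)
    stim_ids: list[str]
    roi: str = ""
    condition: str = ""
    group: str = ""

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _tuning_features(stimulus_set: StimulusSet, stim_ids: list[str], model: str,
                     seed: int) -> np.ndarray:
    """Per-stimulus feature vectors for one tuning model."""
    sel = stimulus_set.select(stim_ids)
    if model == "shape":
        return sel.landmarks.copy()
    if model == "appearance":
        return sel.appearance.copy()
    if model == "view_invariant_appearance":
        return np.array([stimulus_set.canonical_appearance(i) for i in sel.table["identity"]])
    if model == "mirror_symmetry":
        # identity content + a view code that collapses left and right profiles
        codes = {}
        d = 16
        for view in VIEW_ANGLES:
            key = "profile" if view in ("left_profile", "right_profile") else view
            if key not in codes:
                codes[key] = rng_for(seed, "ms_code", key).normal(0.0, 1.0, size=d)
        feats = []
        for _, row in sel.table.iterrows():
            key = "profile" if row["view"] in ("left_profile", "right_profile") else row["view"]
            ident_feat = stimulus_set.canonical_appearance(int(row["identity"]))
            feats.append(np.concatenate([ident_feat, 3.0 * codes[key]]))
        return np.array(feats)
    raise DesignError(f"unknown tuning model {model!r}")


def _mean_pairwise_angle(X: np.ndarray) -> float:
    """Circular mean (degrees) of all pairwise angles between pattern rows."""
    norms = np.linalg.norm(X, axis=1)
    cosmat = (X @ X.T) / np.outer(norms, norms)
    iu = np.triu_indices(X.shape[0], k=1)
    theta = np.degrees(np.arccos(np.clip(cosmat[iu], -1.0, 1.0)))
    rad = np.radians(theta)
    return float(np.degrees(np.arctan2(np.sin(rad).sum(), np.cos(rad).sum())) % 360.0)


def generate_roi_patterns(
    stimulus_set: StimulusSet,
    stim_ids: list[str],
    spec: GeometrySpec,
    roi: str = "",
    condition: str = "",
    shared_latent: np.ndarray | None = None,
    context_coeffs: np.ndarray | None = None,
    pe_component: "PatternSet | None" = None,
    pe_gain: float = 0.0,
) -> PatternSet:
    """Generate stimuli x voxels patterns realizing ``spec``.

    The stimulus-specific part is a linear random projection of the feature
    space selected by ``tuning_weights`` (unit-normalized per model, mixed by
    weight), optionally blended with a shared across-ROI latent and augmented
    with ``extra_context_dims`` orthogonal condition components. A common-mode
    direction is then mixed in with a scalar solved by bisection so the
    noiseless circular-mean pairwise angle hits ``target_mean_angle``.

    If ``pe_component`` is given, its patterns (scaled by ``pe_gain``) are
    added after calibration: use this to build an unexpected condition as
    expected + prediction-error component.
    """
    n = len(stim_ids)
    if n < 2:
        raise DesignError("need at least 2 stimuli")
    v = spec.n_voxels
    if v < n:
        raise DesignError("n_voxels must be >= number of stimuli")

    Z = np.zeros((n, v))
    for model in TUNING_MODELS:
        w = spec.tuning_weights.get(model, 0.0)
        if w == 0.0:
            continue
        F = _tuning_features(stimulus_set, stim_ids, model, seed=spec.seed)
        F = F - F.mean(axis=0, keepdims=True)  # drop the shared component
        if F.shape[1] > v:
            raise DesignError(f"{model} feature dimension exceeds n_voxels")
        # orthonormal projection: an isometric embedding, so the voxel-space
        # Gram equals the feature-space Gram exactly
        P, _ = np.linalg.qr(rng_for(spec.seed, "proj", model).normal(size=(v, F.shape[1])))
        U = F @ P.T
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        Z += w * U

    if spec.shared_weight > 0.0:
        if shared_latent is None:
            raise DesignError("shared_weight > 0 requires shared_latent")
        if shared_latent.shape[1] > v:
            raise DesignError("shared latent dimension exceeds n_voxels")
        P, _ = np.linalg.qr(
            rng_for(spec.seed, "proj", "shared").normal(size=(v, shared_latent.shape[1])))
        G = shared_latent @ P.T
        G /= np.linalg.norm(G, axis=1, keepdims=True)
        Z = (1.0 - spec.shared_weight) * Z + spec.shared_weight * G

    if spec.extra_context_dims > 0:
        k = spec.extra_context_dims
        rngc = rng_for(spec.seed, "context")
        Q, _ = np.linalg.qr(rngc.normal(size=(v, k)))
        # scale each context dimension to the typical dominant eigenvalue of
        # the existing stimulus geometry, so k dims raise PR by roughly k
        Zc = Z - Z.mean(axis=0, keepdims=True)
        lam = np.linalg.eigvalsh(Zc @ Zc.T / max(n - 1, 1))
        lam = np.clip(lam, 0.0, None)
        scale = float(np.sqrt(np.square(lam).sum() / lam.sum())) if lam.sum() > 0 else 1.0
        if context_coeffs is not None:
            if context_coeffs.shape != (n, k):
                raise DesignError("context_coeffs must be (n_stimuli, extra_context_dims)")
            C = context_coeffs * scale
        else:
            C = rngc.normal(0.0, 1.0, size=(n, k)) * scale
        Z = Z + C @ Q.T

    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    m = rng_for(spec.seed, "common").normal(0.0, 1.0, size=v)
    m /= np.linalg.norm(m)

    def realized(c: float) -> float:
        return _mean_pairwise_angle(m[None, :] + c * Z)

    hi = 1e4
    max_angle = realized(hi)
    if spec.target_mean_angle > max_angle + 2.0:
        raise DesignError(
            f"target angle {spec.target_mean_angle} deg unreachable; geometry "
            f"saturates at {max_angle:.1f} deg")
    lo_c, hi_c = 1e-6, hi
    for _ in range(200):
        mid = np.sqrt(lo_c * hi_c)
        if realized(mid) < spec.target_mean_angle:
            lo_c = mid
        else:
            hi_c = mid
        if hi_c / lo_c < 1 + 1e-12:
            break
    c = np.sqrt(lo_c * hi_c)

    X = m[None, :] + c * Z
    X *= spec.amplitude_gain * np.sqrt(v) / np.linalg.norm(X, axis=1).mean()
    if pe_component is not None and pe_gain != 0.0:
        if pe_component.data.shape != X.shape:
            raise DesignError("pe_component shape mismatch")
        X = X + pe_gain * pe_component.data
    if spec.noise_sd > 0.0:
        nseed = spec.seed if spec.noise_seed is None else spec.noise_seed
        noise = rng_for(nseed, "noise").normal(0.0, spec.noise_sd, size=X.shape)
        X = X + noise / np.sqrt(spec.n_trials)
    return PatternSet(data=X, stim_ids=list(stim_ids), roi=roi, condition=condition)


# ---------------------------------------------------------------------------
# BOLD runs
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    data: np.ndarray         # (n_voxels, n_timepoints)
    tr: float
    truth_betas: np.ndarray  # (n_trials, n_voxels), for recovery tests only
    onsets: np.ndarray       # (n_trials,) seconds
    nuisance: np.ndarray | None = None


def generate_bold_timeseries(
    trial_sequence: TrialSequence,
    betas: np.ndarray,
    hrf: np.ndarray,
    tr: float = 2.0,
    noise_sd: float = 0.0,
    ar_coef: float = 0.4,
    seed: int = 0,
    pad_s: float = 24.0,
) -> BoldRun:
    """Event-related BOLD: each trial's pattern enters as its beta, an
    HRF-convolved stick at the trial onset; AR(1)+white noise is added."""
    onsets = trial_sequence.table["onset"].to_numpy(dtype=float)
    if betas.shape[0] != onsets.size:
        raise DesignError("betas must have one row per trial")
    if np.any(np.diff(np.sort(onsets)) < STIMULUS_DURATION - 1e-9):
        raise DesignError("overlapping stimuli: onsets closer than the stimulus duration")
    n_t = int(np.ceil((onsets.max() + pad_s) / tr))
    n_vox = betas.shape[1]
    design = np.zeros((onsets.size, n_t))
    for i, on in enumerate(onsets):
        idx = int(round(on / tr))
        if abs(on - idx * tr) > 1e-6:
            raise DesignError(f"trial onset {on} not on the TR grid")
        stick = np.zeros(n_t)
        stick[idx] = 1.0
        design[i] = np.convolve(stick, hrf)[:n_t]
    data = betas.T @ design  # (n_vox, n_t)
    if noise_sd > 0.0:
        rng = rng_for(seed, "bold_noise")
        white = rng.normal(0.0, noise_sd, size=(n_vox, n_t))
        from scipy.signal import lfilter
        data = data + lfilter([1.0], [1.0, -ar_coef], white, axis=1)
    return BoldRun(data=data, tr=tr, truth_betas=betas.copy(), onsets=onsets)


# ---------------------------------------------------------------------------
# Pupil traces
# ---------------------------------------------------------------------------

@dataclass
class PupilTrace:
    samples: np.ndarray          # pupil area, a.u.; NaN marks blinks/dropouts
    rate_hz: float
    image_onsets: np.ndarray     # s
    pair_onsets: np.ndarray      # s
    block_bounds: list[tuple[float, float]]
    entrainment_strength: float


def _pupil_kernel(rate_hz: float, tau: float = 0.6, power: float = 2.0,
                  length_s: float = 4.0) -> np.ndarray:
    t = np.arange(0.0, length_s, 1.0 / rate_hz)
    k = t**power * np.exp(-t / tau)
    return k / k.max()


def generate_pupil_trace(
    training_sequence: TrialSequence,
    entrainment_strength: float = 1.0,
    noise_sd: float = 40.0,
    rate_hz: float = 120.0,
    seed: int = 0,
    pairs_per_block: int = 16,
    block_gap_s: float = 10.0,
    drift_sd: float = 0.3,
    blink_rate_hz: float = 0.05,
    image_response_mean: float = 0.3,
    image_response_sd: float = 0.5,
    image_latency_sd_s: float = 0.15,
) -> PupilTrace:
    """Pupil area trace for a 1 Hz training stream arranged into blocks.

    Components: a slow drift, a stimulus-evoked dilation at every image onset
    (amplitude and latency jittered per image, so the 1 Hz image response is
    only partially phase-locked), a smooth oscillatory component time-locked
    to *pair* onsets scaled by ``entrainment_strength`` (the 0.5 Hz learning
    signature; an anticipatory modulation at the pair rate, free of higher
    harmonics), white noise, and occasional blinks written as NaN dropouts.
    """
    if rate_hz < 60:
        raise DesignError("rate_hz must be >= 60")
    rng = rng_for(seed, "pupil")
    tab = training_sequence.table
    pair_starts = tab.loc[tab["role"] == "predictor", "onset"].to_numpy()
    n_pairs = pair_starts.size

    # re-time pairs into blocks separated by gaps, preserving the 2 s pair
    # rate; the first two pairs of each block are warm-up (outside the block
    # bounds) so the evoked response is in steady state when epoching starts
    n_warmup = 2
    image_onsets, pair_onsets, block_bounds = [], [], []
    t = 4.0  # leading baseline
    for b in range(0, n_pairs, pairs_per_block + n_warmup):
        k = min(pairs_per_block + n_warmup, n_pairs - b)
        for j in range(k):
            on = t + 2.0 * j
            image_onsets.extend([on, on + 1.0])
            if j >= n_warmup:
                pair_onsets.append(on)
        if k > n_warmup:
            block_bounds.append((t + 2.0 * n_warmup, t + 2.0 * k))
        t += 2.0 * k + block_gap_s
    duration = t + 4.0
    n = int(round(duration * rate_hz))
    time = np.arange(n) / rate_hz

    kernel = _pupil_kernel(rate_hz)
    x = np.zeros(n)
    for on in image_onsets:
        jit = image_latency_sd_s * rng.standard_normal()
        i = max(0, int(round((on + jit) * rate_hz)))
        if i >= n:
            continue
        amp = max(0.0, image_response_mean + image_response_sd * rng.standard_normal())
        seg = kernel[: n - i]
        x[i:i + seg.size] += amp * seg
    if entrainment_strength != 0.0:
        pair_hz = 0.5  # half the 1 Hz image rate
        for b0, b1 in block_bounds:
            # entrainment spans the warm-up pairs too (4 s = 2 full cycles
            # earlier, so the phase at the block bound is unchanged)
            i0 = max(0, int(round((b0 - 2.0 * n_warmup) * rate_hz)))
            i1 = min(n, int(round(b1 * rate_hz)))
            t_block = time[i0:i1] - b0  # pair onsets sit on the 2 s grid from b0
            x[i0:i1] += entrainment_strength * np.sin(2 * np.pi * pair_hz * t_block)

    if drift_sd > 0:
        # knot times are irregular: regular spacing would plant kinks on the
        # 2 s pair grid and leak phase-locked power into the pair frequency
        n_knots = max(4, int(duration / 20.0))
        kt = np.sort(rng.uniform(0.0, duration, size=n_knots))
        kt[0], kt[-1] = 0.0, duration
        x = x + np.interp(time, kt, rng.normal(0.0, drift_sd, size=n_knots))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)

    if blink_rate_hz > 0:
        n_blinks = rng.poisson(blink_rate_hz * duration)
        for _ in range(n_blinks):
            start = rng.uniform(0.0, duration - 0.5)
            width = rng.uniform(0.08, 0.3)
            i0 = int(start * rate_hz)
            i1 = min(n, i0 + max(1, int(width * rate_hz)))
            x[i0:i1] = np.nan

    return PupilTrace(
        samples=x + 3.0,  # arbitrary baseline pupil area
        rate_hz=rate_hz,
        image_onsets=np.array(image_onsets),
        pair_onsets=np.array(pair_onsets),
        block_bounds=block_bounds,
        entrainment_strength=entrainment_strength,
    )


# ---------------------------------------------------------------------------
# Low-level stimulus balance
# ---------------------------------------------------------------------------

def stimulus_balance_check(features_by_role: dict[str, np.ndarray]):
    """Two-sample t-test comparing within-role pairwise feature distances.

    With 9 stimuli per role this gives 36 distances per role and df = 70,
    the design check that predictor and successor stimulus sets do not differ
    in feature-space spread.
    Returns (t, df, p).
    """
    if len(features_by_role) != 2:
        raise DesignError("exactly two roles required")
    dists = []
    for role, F in features_by_role.items():
        F = np.asarray(F, dtype=float)
        if F.shape[0] < 3:
            raise DesignError(f"role {role!r} needs >= 3 stimuli for >= 2 distances")
        dists.append(pdist(F))
    res = ttest_ind(dists[0], dists[1])
    df = dists[0].size + dists[1].size - 2
    return float(res.statistic), int(df), float(res.pvalue)
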