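"""Generator invariants: design constants, determinism, balance, geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patsep.synthdata import (
    INTER_PAIR_JITTERS,
    INTRA_PAIR_JITTERS,
    TRAINED_VIEWS,
    DesignError,
    GeometrySpec,
    build_pairs,
    generate_pupil_trace,
    generate_roi_patterns,
    generate_stimulus_set,
    generate_test_sequence,
    generate_training_sequence,
    stimulus_balance_check,
)


class TestStimulusSet:
    def test_trained_set_counts(self):
        s = generate_stimulus_set(18, TRAINED_VIEWS, L_landmarks=68, A_features=50, seed=1)
        assert s.n_stimuli == 54
        assert s.landmarks.shape == (54, 2 * 68)

    def test_same_seed_bit_identical(self):
        a = generate_stimulus_set(seed=3)
        b = generate_stimulus_set(seed=3)
        assert np.array_equal(a.landmarks, b.landmarks)
        assert np.array_equal(a.appearance, b.appearance)
        assert np.array_equal(a.images, b.images)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_minimal_two_identity_case(self):
        s = generate_stimulus_set(2, ("frontal",), seed=0)
        assert s.n_stimuli == 2
        assert set(s.table["role"]) == {"predictor", "successor"}

    def test_odd_identities_rejected(self):
        with pytest.raises(DesignError):
            generate_stimulus_set(17, seed=0)

    def test_frontal_appearance_is_canonical(self, stimuli):
        row = stimuli.table[(stimuli.table["identity"] == 0)
                            & (stimuli.table["view"] == "frontal")].index[0]
        assert np.array_equal(stimuli.appearance[row], stimuli.canonical_appearance(0))

    def test_profiles_not_pixel_mirrors(self, stimuli):
        t = stimuli.table
        for ident in (0, 5):
            left = stimuli.images[t[(t.identity == ident) & (t.view == "left_profile")].index[0]]
            right = stimuli.images[t[(t.identity == ident) & (t.view == "right_profile")].index[0]]
            assert not np.allclose(left, right[:, ::-1], atol=1e-3)

    def test_images_luminance_equalized(self, stimuli):
        means = stimuli.images.mean(axis=(1, 2))
        assert np.allclose(means, 0.5, atol=1e-9)
        assert stimuli.images.min() >= 0.0 and stimuli.images.max() <= 1.0


class TestPairDesign:
    def test_nine_pairs_with_balanced_views(self, stimuli, pair_design):
        assert pair_design.n_pairs == 9

        def view_hist(ids):
            views = [stimuli.table.loc[stimuli.index_of(s), "view"] for s in ids]
            return sorted(np.unique(views, return_counts=True)[1])

        assert view_hist(pair_design.predictor_ids()) == [3, 3, 3]
        assert view_hist(pair_design.predictor_ids()) == view_hist(pair_design.successor_ids())

    def test_no_novelty_in_violations(self, pair_design):
        successors = set(pair_design.successor_ids())
        for p in pair_design.pairs:
            assert p["unexpected_identity"] in successors
            assert p["unexpected_identity"] != p["successor"]

    def test_unexpected_views_are_untrained_same_identity(self, stimuli, pair_design):
        for p in pair_design.pairs:
            succ_row = stimuli.table.loc[stimuli.index_of(p["successor"])]
            for uid in p["unexpected_views"]:
                row = stimuli.table.loc[stimuli.index_of(uid)]
                assert row["identity"] == succ_row["identity"]
                assert not row["trained"]


class TestTrainingSequence:
    def test_within_pair_transition_probability_is_one(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=5, seed=2)
        tab = seq.table
        preds = tab[tab.role == "predictor"].reset_index()
        succ_lookup = {p["predictor"]: p["successor"] for p in pair_design.pairs}
        for _, row in preds.iterrows():
            nxt = tab.iloc[row["index"] + 1]
            assert nxt["stim_id"] == succ_lookup[row["stim_id"]]

    def test_single_repeat_covers_each_pair_once(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=1, seed=0)
        counts = seq.table[seq.table.role == "predictor"]["pair_index"].value_counts()
        assert (counts == 1).all() and len(counts) == 9

    def test_between_pair_transitions_near_uniform(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=100, seed=4)
        order = seq.table[seq.table.role == "predictor"]["pair_index"].to_numpy()
        trans = np.zeros((9, 9))
        for a, b in zip(order[:-1], order[1:]):
            trans[a, b] += 1
        off = trans[~np.eye(9, dtype=bool)]
        assert off.max() / max(off.min(), 1) <= 2.0


class TestTestSequence:
    def test_exact_condition_counts(self, pair_design):
        seq = generate_test_sequence(pair_design, (0.6, 0.2, 0.2), n_trials=90, seed=3)
        succ = seq.table[seq.table.role == "successor"]
        counts = succ["condition"].value_counts()
        assert counts["expected"] == 54
        assert counts["unexpected_identity"] == 18
        assert counts["unexpected_view"] == 18

    def test_degenerate_proportions_all_expected(self, pair_design):
        seq = generate_test_sequence(pair_design, (1.0, 0.0, 0.0), n_trials=18, seed=3)
        succ = seq.table[seq.table.role == "successor"]
        assert (succ["condition"] == "expected").all()

    def test_baselines_from_jitter_sets_and_tr_grid(self, pair_design):
        seq = generate_test_sequence(pair_design, n_trials=90, seed=9)
        tab = seq.table
        intra = tab.loc[tab.role == "predictor", "baseline_after"]
        inter = tab.loc[tab.role == "successor", "baseline_after"]
        assert set(intra) <= set(INTRA_PAIR_JITTERS)
        assert set(inter) <= set(INTER_PAIR_JITTERS)
        assert np.allclose(np.mod(tab["onset"], seq.tr), 0.0, atol=1e-9)

    def test_unrealizable_counts_rejected(self, pair_design):
        with pytest.raises(DesignError, match="realizable"):
            generate_test_sequence(pair_design, (0.6, 0.2, 0.2), n_trials=91, seed=0)


class TestRoiPatterns:
    def test_target_angle_realized_noiseless(self, stimuli, pair_design):
        from patsep.separability import circular_mean_angle, pairwise_angles
        for target in (45.0, 60.0, 75.0, 85.0):
            spec = GeometrySpec(tuning_weights={"view_invariant_appearance": 1.0},
                                target_mean_angle=target, noise_sd=0.0, seed=5)
            ps = generate_roi_patterns(stimuli, pair_design.successor_ids(), spec)
            mean = circular_mean_angle(pairwise_angles(ps))
            assert abs(mean - target) < 2.0

    def test_mirror_weights_make_profiles_identical(self, stimuli):
        t = stimuli.table
        ids = []
        for ident in range(3):
            for view in TRAINED_VIEWS:
                ids.append(t[(t.identity == ident) & (t.view == view)]["stim_id"].iloc[0])
        spec = GeometrySpec(tuning_weights={"mirror_symmetry": 1.0},
                            target_mean_angle=60.0, noise_sd=0.0, seed=5)
        ps = generate_roi_patterns(stimuli, ids, spec)
        for ident in range(3):
            left = ps.data[ids.index(f"id{ident:02d}_left_profile")]
            right = ps.data[ids.index(f"id{ident:02d}_right_profile")]
            assert np.allclose(left, right, atol=1e-10)

    def test_context_dims_raise_dimensionality(self, stimuli, pair_design):
        from patsep.dimensionality import participation_ratio
        # shape tuning is view-clustered, hence low-dimensional without context
        base = GeometrySpec(tuning_weights={"shape": 1.0},
                            target_mean_angle=60.0, noise_sd=0.0, seed=5)
        with_ctx = GeometrySpec(tuning_weights={"shape": 1.0},
                                target_mean_angle=60.0, noise_sd=0.0, seed=5,
                                extra_context_dims=6)
        ids = pair_design.successor_ids()
        pr0 = participation_ratio(generate_roi_patterns(stimuli, ids, base)).pr
        pr4 = participation_ratio(generate_roi_patterns(stimuli, ids, with_ctx)).pr
        assert pr4 > pr0 + 1.5

    def test_unreachable_target_raises(self, stimuli, pair_design):
        spec = GeometrySpec(tuning_weights={"view_invariant_appearance": 1.0},
                            target_mean_angle=178.0, noise_sd=0.0, seed=5)
        with pytest.raises(DesignError, match="unreachable"):
            generate_roi_patterns(stimuli, pair_design.successor_ids(), spec)

    def test_bad_weights_rejected(self):
        with pytest.raises(DesignError):
            GeometrySpec(tuning_weights={"shape": 0.5}, target_mean_angle=60.0)
        with pytest.raises(DesignError):
            GeometrySpec(tuning_weights={"shape": 1.0}, target_mean_angle=0.0)


class TestPupilTraceGenerator:
    def test_deterministic(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=40, seed=1)
        a = generate_pupil_trace(seq, seed=2)
        b = generate_pupil_trace(seq, seed=2)
        assert np.array_equal(a.samples, b.samples, equal_nan=True)

    def test_rate_floor_enforced(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=40, seed=1)
        with pytest.raises(DesignError):
            generate_pupil_trace(seq, rate_hz=30.0)

    def test_strong_entrainment_dominates_pair_frequency(self, pair_design):
        seq = generate_training_sequence(pair_design, n_repeats=40, seed=1)
        trace = generate_pupil_trace(seq, entrainment_strength=30.0, noise_sd=0.0,
                                     drift_sd=0.0, blink_rate_hz=0.0, seed=3)
        b0, b1 = trace.block_bounds[0]
        fs = trace.rate_hz
        seg = trace.samples[int(b0 * fs):int(b1 * fs)]
        seg = seg - seg.mean()
        freqs = np.fft.rfftfreq(seg.size, 1 / fs)
        power = np.abs(np.fft.rfft(seg)) ** 2
        assert abs(freqs[np.argmax(power)] - 0.5) < 1e-6


class TestStimulusBalance:
    def test_identical_feature_sets_give_t_zero(self, rng):
        F = rng.normal(size=(9, 20))
        t, df, p = stimulus_balance_check({"predictor": F, "successor": F.copy()})
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_nine_per_role_gives_df_70(self, rng):
        t, df, p = stimulus_balance_check({"a": rng.normal(size=(9, 20)),
                                           "b": rng.normal(size=(9, 20))})
        assert df == 70

    def test_matches_textbook_two_sample_t(self, rng):
        from scipy.spatial.distance import pdist
        Fa, Fb = rng.normal(size=(8, 10)), rng.normal(size=(7, 10))
        t, df, p = stimulus_balance_check({"a": Fa, "b": Fb})
        da, db = pdist(Fa), pdist(Fb)
        na, nb = da.size, db.size
        sp = np.sqrt(((na - 1) * da.var(ddof=1) + (nb - 1) * db.var(ddof=1)) / (na + nb - 2))
        t_ref = (da.mean() - db.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == na + nb - 2

    def test_role_sets_are_feature_balanced(self, stimuli):
        # the generator's orthogonal-rotation construction: same spread per role
        tab = stimuli.table
        feats = {}
        for role in ("predictor", "successor"):
            mask = (tab.role == role) & tab.trained
            feats[role] = stimuli.appearance[tab.index[mask]]
        t, df, p = stimulus_balance_check(feats)
        assert p > 0.05
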