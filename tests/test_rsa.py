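"""RDM construction, 2nd-level inference, correlation contrasts, PE geometry."""

import numpy as np
import pytest
from scipy import stats

from patsep import rsa
from patsep.synthdata import PatternSet


def _ps(X, **kw):
    return PatternSet(data=np.asarray(X, dtype=float),
                      stim_ids=[f"s{i}" for i in range(len(X))], **kw)


class TestFirstLevelRdm:
    def test_orthogonal_and_identical_pairs(self):
        X = np.array([[1.0, 0, 0], [0, 1.0, 0], [2.0, 0, 0]])
        rdm = rsa.first_level_rdm(_ps(X))
        assert rdm.matrix[0, 1] == pytest.approx(1.0)
        assert rdm.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_consistency_with_angle_module(self, rng):
        from patsep.separability import pairwise_angles
        ps = _ps(rng.normal(size=(8, 25)))
        rdm = rsa.first_level_rdm(ps)
        angles = pairwise_angles(ps)
        iu = np.triu_indices(8, k=1)
        theta_from_rdm = np.degrees(np.arccos(1.0 - rdm.matrix[iu]))
        assert np.allclose(np.sort(theta_from_rdm), np.sort(angles.angles), atol=1e-9)

    def test_symmetric_zero_diagonal_enforced(self, rng):
        rdm = rsa.first_level_rdm(_ps(rng.normal(size=(6, 10))))
        assert np.allclose(rdm.matrix, rdm.matrix.T)
        assert np.allclose(np.diag(rdm.matrix), 0.0)


class TestModelRdms:
    def test_shape_rdm_identical_and_reversed_vectors(self):
        from patsep.rsa import _spearman_distance_rdm
        v = np.arange(10.0)
        rdm = _spearman_distance_rdm(np.stack([v, v, v[::-1]]), ["a", "b", "c"])
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[0, 2] == pytest.approx(2.0)

    def test_spearman_distance_matches_scipy(self, rng):
        from patsep.rsa import _spearman_distance_rdm
        F = rng.normal(size=(7, 30))
        rdm = _spearman_distance_rdm(F, [f"s{i}" for i in range(7)])
        for i in range(7):
            for j in range(i + 1, 7):
                ref = 1.0 - stats.spearmanr(F[i], F[j]).statistic
                assert rdm.matrix[i, j] == pytest.approx(ref, abs=1e-10)

    def test_constant_vector_rejected(self):
        from patsep.rsa import _spearman_distance_rdm
        F = np.ones((4, 6))
        with pytest.raises(ValueError, match="constant"):
            _spearman_distance_rdm(F, list("abcd"))

    def test_mirror_symmetry_binary_structure(self):
        views = ["frontal", "frontal", "left_profile", "right_profile"]
        rdm = rsa.model_rdm_mirror_symmetry(views, list("abcd"))
        assert rdm.matrix[0, 1] == 0.0          # same view
        assert rdm.matrix[2, 3] == 0.0          # left vs right profile
        assert rdm.matrix[0, 2] == 1.0          # frontal vs profile
        with pytest.raises(ValueError):
            rsa.model_rdm_mirror_symmetry(["frontal", "sideways", "frontal"])

    def test_view_invariant_rdm_ignores_view(self, stimuli):
        tab = stimuli.table
        ids = []
        for ident in (0, 1, 2):
            for view in ("frontal", "left_profile", "right_profile"):
                ids.append(tab[(tab.identity == ident) & (tab.view == view)]["stim_id"].iloc[0])
        sel = stimuli.select(ids)
        rdm = rsa.model_rdm_view_invariant_appearance(sel, stimuli)
        M = rdm.matrix
        # same identity across views: zero distance
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)
        # identity-pair distance identical for every view combination
        vals = [M[i, j] for i in range(3) for j in range(3, 6)]
        assert np.ptp(vals) < 1e-12

    def test_appearance_rdm_zero_for_same_stimulus_features(self, stimuli):
        sel = stimuli.select([stimuli.table["stim_id"].iloc[0],
                              stimuli.table["stim_id"].iloc[1],
                              stimuli.table["stim_id"].iloc[2]])
        rdm = rsa.model_rdm_appearance(sel)
        assert np.allclose(np.diag(rdm.matrix), 0.0)
        assert np.allclose(rdm.matrix, rdm.matrix.T)


class TestGaborControl:
    def test_identical_images_zero_distance(self, stimuli):
        sel = stimuli.select(list(stimuli.table["stim_id"].iloc[:3]))
        sel.images[1] = sel.images[0]
        rdm = rsa.gabor_control_rdm(sel)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_sensitivity_and_translation_tolerance(self, stimuli):
        img = stimuli.images[0]
        rotated = np.rot90(img)
        translated = np.roll(img, 1, axis=1)
        F = rsa.gabor_features(np.stack([img, rotated, translated]))
        d_rot = np.linalg.norm(F[0] - F[1])
        d_trans = np.linalg.norm(F[0] - F[2])
        assert d_rot > 0
        assert d_trans < d_rot


class TestSecondLevel:
    def _toy(self, rng, n=9):
        X = rng.normal(size=(n, 60))
        first = rsa.first_level_rdm(_ps(X))
        return X, first

    def test_self_model_gives_rho_one(self, rng):
        _, first = self._toy(rng)
        model = rsa.RDM(matrix=first.matrix.copy(), labels=first.labels, level="model")
        fits = rsa.second_level_fit(first, {"self": model}, None, n_boot=50, seed=1)
        assert fits.fits["self"].rho == pytest.approx(1.0)

    def test_independent_rdms_give_rho_near_zero(self, rng):
        rhos = []
        for _ in range(40):
            _, first = self._toy(rng)
            _, other = self._toy(rng)
            other.level = "model"
            fits = rsa.second_level_fit(first, {"m": other}, None, n_boot=1, seed=1)
            rhos.append(fits.fits["m"].rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_bootstrap_length_matches_request(self, rng):
        _, first = self._toy(rng)
        _, other = self._toy(rng)
        other.level = "model"
        fits = rsa.second_level_fit(first, {"m": other}, None, n_boot=250, seed=2)
        assert fits.fits["m"].bootstrap_z.shape == (250,)

    def test_partial_correlation_removes_planted_confound(self, rng, stimuli, pair_design):
        """Mixing the low-level RDM into the 1st level leaves the partial rho
        for the true model within +-0.05 of its confound-free value."""
        ids = pair_design.predictor_ids()
        sel = stimuli.select(ids)
        control = rsa.gabor_control_rdm(sel)
        model = rsa.model_rdm_shape(sel)
        base = 0.8 * model.matrix / model.matrix.max()
        confounded = base + 0.5 * control.matrix / control.matrix.max()
        rdm_clean = rsa.RDM(matrix=base, labels=model.labels)
        rdm_conf = rsa.RDM(matrix=confounded, labels=model.labels)
        rho_clean = rsa.second_level_fit(rdm_clean, {"shape": model}, control,
                                         n_boot=1, seed=0).fits["shape"].rho
        rho_conf = rsa.second_level_fit(rdm_conf, {"shape": model}, control,
                                        n_boot=1, seed=0).fits["shape"].rho
        assert abs(rho_conf - rho_clean) < 0.05


class TestBestModel:
    def test_true_model_wins_with_floor_p(self, rng):
        X = rng.normal(size=(9, 60))
        first = rsa.first_level_rdm(_ps(X))
        true_model = rsa.RDM(matrix=first.matrix.copy(), labels=first.labels, level="model")
        others = {}
        for k in range(3):
            Y = rng.normal(size=(9, 60))
            others[f"r{k}"] = rsa.RDM(matrix=rsa.first_level_rdm(_ps(Y)).matrix,
                                      labels=first.labels, level="model")
        fits = rsa.second_level_fit(first, {"true": true_model, **others}, None,
                                    n_boot=400, seed=3)
        diff, p = rsa.best_model_test(fits, "true")
        assert diff > 0
        assert p < 0.01

    def test_identical_models_give_symmetric_p(self, rng):
        X = rng.normal(size=(9, 60))
        first = rsa.first_level_rdm(_ps(X))
        m = rsa.RDM(matrix=first.matrix.copy(), labels=first.labels, level="model")
        m2 = rsa.RDM(matrix=first.matrix.copy(), labels=first.labels, level="model")
        fits = rsa.second_level_fit(first, {"a": m, "b": m2}, None, n_boot=200, seed=4)
        diff, p = rsa.best_model_test(fits, "a")
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert 0.3 < p <= 1.0  # ties resolve to a large one-sided p


class TestRaghunathan:
    def test_equal_correlations_give_z_zero(self):
        inter = {"r_jh": 0.3, "r_jm": 0.2, "r_kh": 0.2, "r_km": 0.3}
        z, p = rsa.raghunathan_test(0.4, 0.4, inter, n=50, alternative="two-sided")
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        inter = {"r_jh": 0.3, "r_jm": 0.1, "r_kh": 0.2, "r_km": 0.25}
        inter_sw = {"r_jh": 0.3, "r_jm": 0.2, "r_kh": 0.1, "r_km": 0.25}
        z1, _ = rsa.raghunathan_test(0.5, 0.2, inter, n=40, alternative="two-sided")
        z2, _ = rsa.raghunathan_test(0.2, 0.5, inter_sw, n=40, alternative="two-sided")
        assert z1 == pytest.approx(-z2, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        inter = {"r_jh": 0.0, "r_jm": 0.0, "r_kh": 0.0, "r_km": 0.0}
        with pytest.raises(ValueError):
            rsa.raghunathan_test(1.0, 0.2, inter, n=50)
        with pytest.raises(ValueError):
            rsa.raghunathan_test(0.5, 0.2, inter, n=5)

    def test_null_calibration(self):
        """Type-I error near 0.05 under a 4-variate normal null (r_jk == r_hm)."""
        rng = np.random.default_rng(45)
        n, n_sim = 60, 2000
        # common covariance: corr(j,k) == corr(h,m) == 0.4, cross-corrs 0.2
        C = np.full((4, 4), 0.2)
        np.fill_diagonal(C, 1.0)
        C[0, 1] = C[1, 0] = 0.4
        C[2, 3] = C[3, 2] = 0.4
        L = np.linalg.cholesky(C)
        hits = 0
        for _ in range(n_sim):
            X = rng.normal(size=(n, 4)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            inter = {"r_jh": R[0, 2], "r_jm": R[0, 3], "r_kh": R[1, 2], "r_km": R[1, 3]}
            _, p = rsa.raghunathan_test(R[0, 1], R[2, 3], inter, n=n,
                                        alternative="two-sided")
            hits += p < 0.05
        assert 0.03 <= hits / n_sim <= 0.07


class TestFisherIndependent:
    def test_equal_correlations(self):
        z, p = rsa.fisher_independent_test(0.3, 50, 0.3, 40, alternative="two-sided")
        assert z == pytest.approx(0.0)

    def test_closed_form(self):
        z, _ = rsa.fisher_independent_test(0.5, 50, 0.0, 50)
        ref = np.arctanh(0.5) / np.sqrt(2.0 / 47.0)
        assert z == pytest.approx(ref, abs=1e-12)

    def test_swapping_samples_negates_z(self, rng):
        for _ in range(50):
            r1, r2 = rng.uniform(-0.9, 0.9, 2)
            n1, n2 = rng.integers(5, 100, 2)
            z1, _ = rsa.fisher_independent_test(r1, int(n1), r2, int(n2))
            z2, _ = rsa.fisher_independent_test(r2, int(n2), r1, int(n1))
            assert z1 == pytest.approx(-z2, abs=1e-12)


class TestPeGeometry:
    def test_identity_pe_rdm_has_36_entries(self, rng):
        exp = _ps(rng.normal(size=(9, 40)))
        unexp = _ps(rng.normal(size=(9, 40)))
        pes, rdm = rsa.pe_geometry(exp, unexp, "identity")
        assert rdm.vector().size == 36
        assert pes.data.shape == (9, 40)

    def test_degenerate_pe_flagged(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError, match="degenerate PE"):
            rsa.pe_geometry(_ps(X), _ps(X.copy()), "identity")

    def test_pe_component_tuning_recovered_in_al_analog(self, study):
        """PE differences in the AL analog carry appearance-family structure:
        the appearance-based models outrank the feedforward models."""
        from patsep.pipeline import _model_rdms_for
        exp = study["patterns"][("AL", "expected")]
        unexp = study["patterns"][("AL", "unexpected")]
        _, pe_rdm = rsa.pe_geometry(exp, unexp, "identity")
        models = _model_rdms_for(study["stimuli"], study["stim_by_cond"]["expected"])
        v1 = pe_rdm.vector()
        rhos = {m: rsa._partial_spearman(v1, md.vector(), None) for m, md in models.items()}
        app_family = max(rhos["appearance"], rhos["view_invariant_appearance"])
        assert app_family > rhos["shape"]
        assert app_family > rhos["mirror_symmetry"]

    def test_mismatched_stimuli_rejected(self, rng):
        a = _ps(rng.normal(size=(4, 6)))
        b = PatternSet(data=rng.normal(size=(4, 6)), stim_ids=list("wxyz"))
        with pytest.raises(ValueError):
            rsa.pe_geometry(a, b, "identity")
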