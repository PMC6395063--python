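"""Decoding pipeline: pairing, PCA, balancing, classification, the
representation-strength statistic, residualisation, searchlight, bias guard."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entroscope import glm, mvpa
from entroscope.synthetic import NeuralGenConfig, PatternMatrix, generate_state_region_patterns


STANDARD_AVAIL = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 2, 3), (4, 5, 6, 7)]


class TestPairRuns:
    def test_standard_availability_pairs_across_halves(self):
        folds = mvpa.pair_runs_split(STANDARD_AVAIL)
        assert len(folds) == 2
        (tr1, te1), (tr2, te2) = folds
        assert tr1 == te2 and te1 == tr2
        for pair in (tr1, te1):
            covered = set(STANDARD_AVAIL[pair[0]]) | set(STANDARD_AVAIL[pair[1]])
            assert covered == set(range(8))

    def test_every_trial_tested_exactly_once(self):
        folds = mvpa.pair_runs_split(STANDARD_AVAIL)
        test_runs = [r for _, te in folds for r in te]
        assert sorted(test_runs) == [0, 1, 2, 3]

    def test_uncoverable_availability_raises(self):
        avail = [(0, 1, 2, 3)] * 4  # options 4-7 never shown
        with pytest.raises(ValueError, match="4, 5, 6, 7"):
            mvpa.pair_runs_split(avail)


class TestReduceDimensions:
    def test_low_rank_data_reconstructs_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((3, 40))
        X = rng.standard_normal((60, 3)) @ basis
        red = mvpa.reduce_dimensions(X, k=20)
        assert red.components.shape[0] == 3  # capped at rank
        recon = red.loadings @ red.components + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-8)
        gram = red.components @ red.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            mvpa.reduce_dimensions(np.zeros((5, 5)), k=0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_reconstruction_error_nonincreasing_in_k(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 12))
        errs = []
        for k in (1, 3, 6, 12):
            red = mvpa.reduce_dimensions(X, k=k)
            recon = red.loadings @ red.components + X.mean(axis=0)
            errs.append(float(((X - recon) ** 2).sum()))
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


class TestBalancing:
    def test_counts_equalised_by_cycling(self):
        labels = np.array([0] * 10 + [1] * 7 + [2] * 5 + [3] * 3)
        idx = np.arange(len(labels))
        out = mvpa.balance_training_set(idx, labels)
        _, counts = np.unique(labels[out], return_counts=True)
        assert counts.tolist() == [10, 10, 10, 10]

    def test_balanced_input_unchanged(self):
        labels = np.array([0, 0, 1, 1])
        out = mvpa.balance_training_set(np.arange(4), labels)
        assert sorted(out.tolist()) == [0, 1, 2, 3]

    def test_deterministic(self):
        labels = np.array([0] * 4 + [1] * 2)
        a = mvpa.balance_training_set(np.arange(6), labels)
        b = mvpa.balance_training_set(np.arange(6), labels)
        np.testing.assert_array_equal(a, b)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            mvpa.balance_training_set(np.array([]), np.array([]))


class TestClassifier:
    def test_separable_prototypes_decode_perfectly(self):
        rng = np.random.default_rng(1)
        protos = rng.standard_normal((8, 15)) * 5
        y = np.tile(np.arange(8), 20)
        X = protos[y]
        proba = mvpa.train_and_classify(X, y, X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba.argmax(axis=1) == y).all()

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 10))
        y = rng.integers(0, 8, 400)
        accs = []
        for _ in range(5):
            yp = rng.permutation(y)
            proba = mvpa.train_and_classify(X[:300], yp[:300], X[300:])
            accs.append((proba.argmax(axis=1) == yp[300:]).mean())
        assert abs(np.mean(accs) - 1 / 8) < 0.08

    def test_bitwise_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 6))
        y = rng.integers(0, 8, 100)
        a = mvpa.train_and_classify(X, y, X[:10])
        b = mvpa.train_and_classify(X, y, X[:10])
        np.testing.assert_array_equal(a, b)


class TestRepresentationStrength:
    def test_uniform_probabilities_give_zero(self):
        p = np.full(8, 1 / 8)
        assert mvpa.representation_strength(p, 0, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_hand_computed_log_odds(self):
        """p_chosen = 0.5, rest spread equally: RS = ln 13."""
        p = np.full(8, 0.5 / 7)
        p[0] = 0.5
        rs = mvpa.representation_strength(p, 0, (0, 1, 2, 3))
        assert rs == pytest.approx(np.log(13), abs=1e-6)

    def test_certain_probability_clipped_finite(self):
        p = np.zeros(8)
        p[0] = 1.0
        rs = mvpa.representation_strength(p, 0, (0, 1, 2, 3))
        assert np.isfinite(rs) and rs > 10

    def test_chosen_must_be_available(self):
        with pytest.raises(ValueError):
            mvpa.representation_strength(np.full(8, 1 / 8), 5, (0, 1, 2, 3))

    def test_sum_aggregation_option(self):
        p = np.full(8, 0.5 / 7)
        p[0] = 0.5
        rs_sum = mvpa.representation_strength(p, 0, (0, 1, 2, 3), aggregate="sum")
        rs_mean = mvpa.representation_strength(p, 0, (0, 1, 2, 3), aggregate="mean")
        assert rs_sum < rs_mean  # summed unchosen mass gives longer odds


class TestResidualise:
    def test_orthogonal_nuisance_leaves_patterns(self):
        rng = np.random.default_rng(4)
        acts = rng.standard_normal((50, 8))
        acts -= acts.mean(axis=0)
        nuis = rng.standard_normal(50)
        nuis -= nuis.mean()
        # orthogonalise the nuisance against every voxel
        proj, *_ = np.linalg.lstsq(acts, nuis, rcond=None)
        nuis = nuis - acts @ proj
        pm = PatternMatrix(acts, np.zeros(50, int), np.zeros(50, int))
        out = mvpa.residualize_voxelwise(pm, nuis)
        np.testing.assert_allclose(out.activity, acts, atol=1e-10)

    def test_voxel_equal_to_nuisance_zeroed(self):
        rng = np.random.default_rng(5)
        nuis = rng.standard_normal(40)
        acts = np.column_stack([nuis, rng.standard_normal(40)])
        pm = PatternMatrix(acts, np.zeros(40, int), np.zeros(40, int))
        out = mvpa.residualize_voxelwise(pm, nuis)
        np.testing.assert_allclose(out.activity[:, 0], 0.0, atol=1e-10)

    def test_rank_deficient_nuisance_rejected(self):
        acts = np.random.default_rng(0).standard_normal((20, 3))
        pm = PatternMatrix(acts, np.zeros(20, int), np.zeros(20, int))
        bad = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            mvpa.residualize_voxelwise(pm, bad)

    def test_entropy_effect_survives_value_residualisation(self, small_subject_data):
        """The entropy -> representation-strength effect in a state-coding
        region keeps its sign after removing univariate value signal from
        every voxel (the value-confound control)."""
        sub = small_subject_data
        cfg = NeuralGenConfig(n_voxels=80, noise_sd=1.0)
        pm = generate_state_region_patterns(sub["trials"], sub["beliefs"], cfg,
                                            np.random.default_rng(10))
        value = sub["beliefs"]["ev_chosen"].to_numpy()
        reward_hist = np.column_stack([
            np.roll(sub["trials"]["outcome"].to_numpy(), k) for k in range(4)
        ])
        resid = mvpa.residualize_voxelwise(pm, np.column_stack([value, reward_hist]))
        design = glm.build_design("GLM4", sub["labeled"], sub["beliefs"])
        core = sub["labeled"]["core_exploit"].to_numpy(bool)
        t_res = (
            glm.fit_ols(design, mvpa.repstrength_series(resid, STANDARD_AVAIL), subset=core)
            .set_index("regressor").loc["entropy", "t"]
        )
        assert t_res < -2.0


class TestSearchlight:
    def test_spheres_respect_mask_and_planted_region_peaks(self, small_subject_data):
        sub = small_subject_data
        shape = (6, 6, 6)
        cfg = NeuralGenConfig(n_voxels=216, noise_sd=1.0, volume_shape=shape)
        pm = generate_state_region_patterns(sub["trials"], sub["beliefs"], cfg,
                                            np.random.default_rng(13))
        informative = (pm.coords < 3).all(axis=1)
        rng = np.random.default_rng(14)
        acts = rng.standard_normal(pm.activity.shape) * 1.5
        acts[:, informative] = pm.activity[:, informative]
        pmv = PatternMatrix(acts, pm.labels, pm.runs, pm.coords)

        design = glm.build_design("GLM4", sub["labeled"], sub["beliefs"])
        core = sub["labeled"]["core_exploit"].to_numpy(bool)

        def stat(region):
            rs = mvpa.repstrength_series(region, STANDARD_AVAIL)
            return float(glm.fit_ols(design, rs, subset=core)
                         .set_index("regressor").loc["entropy", "t"])

        mask = np.ones(shape, bool)
        mask[5, 5, 5] = False
        smap = mvpa.searchlight_map(pmv, mask, stat, radius_voxels=2.0, min_voxels=8)
        assert np.isnan(smap[5, 5, 5])
        # negative entropy effect concentrates in/near the informative corner
        inside = np.nanmean(smap[:3, :3, :3])
        outside = np.nanmean(smap[3:, 3:, 3:])
        assert inside < outside
        peak = np.unravel_index(np.nanargmin(smap), shape)
        assert all(c < 3 + 2 for c in peak)  # within one radius of the region


class TestShuffleBiasCheck:
    def test_permutation_preserves_trial_multisets(self, small_subject_data):
        sub = small_subject_data
        cfg = NeuralGenConfig(n_voxels=20, noise_sd=1.0)
        pm = generate_state_region_patterns(sub["trials"], sub["beliefs"], cfg,
                                            np.random.default_rng(17))
        seen = []

        def spy(p):
            seen.append(p.activity.copy())
            return 0.0

        mvpa.shuffle_bias_check(pm, spy, np.random.default_rng(0), n_perm=10, observed=0.0)
        for shuffled in seen:
            np.testing.assert_allclose(np.sort(shuffled, axis=1),
                                       np.sort(pm.activity, axis=1))
            assert not np.allclose(shuffled, pm.activity)

    def test_small_n_perm_warns(self, small_subject_data):
        sub = small_subject_data
        cfg = NeuralGenConfig(n_voxels=10, noise_sd=1.0)
        pm = generate_state_region_patterns(sub["trials"], sub["beliefs"], cfg,
                                            np.random.default_rng(18))
        with pytest.warns(UserWarning):
            mvpa.shuffle_bias_check(pm, lambda p: 0.0, np.random.default_rng(0),
                                    n_perm=5, observed=0.0)


def test_decode_accuracy_higher_on_low_entropy_trials(small_subject_data):
    """State-coding regions decode better when the model is certain; the
    decoder's confidence in the chosen option tracks belief concentration."""
    sub = small_subject_data
    cfg = NeuralGenConfig(n_voxels=80, noise_sd=1.0)
    pm = generate_state_region_patterns(sub["trials"], sub["beliefs"], cfg,
                                        np.random.default_rng(19))
    proba = mvpa.decode_patterns(pm, STANDARD_AVAIL)
    acc = proba.argmax(axis=1) == pm.labels
    ent = sub["beliefs"]["entropy"].to_numpy()
    low = ent < np.median(ent)
    assert acc[low].mean() > acc[~low].mean()
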