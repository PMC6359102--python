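import numpy as np
import pandas as pd
import pytest

from stressvr.kernels import KernelSpec, compute_kernel_matrices, kernel_space_distance
from stressvr.svr import fit_weighted_svr, predict_svr
from stressvr.transduction import (
    LabeledExample,
    TransductiveConfig,
    dispersion_scores,
    predict_transductive,
    run_st_svr,
    run_t_svr,
    select_neighborhood,
)

from oracles import exhaustive_selection_minimum


def _cfg(**kw):
    kw.setdefault("kernel", KernelSpec(gamma=1.0))
    return TransductiveConfig(**kw)


class TestDispersionScores:
    def test_median_example_scores_zero(self):
        stats, scores = dispersion_scores([0.2, 0.4, 0.6])
        assert stats.median_y == 0.4
        assert scores[1] == 0.0

    def test_hand_computed_example(self):
        stats, scores = dispersion_scores([0.0, 0.5, 1.0])
        assert stats.median_y == 0.5
        assert stats.mad_y == 0.5
        assert scores[2] == pytest.approx(1.0)

    def test_identical_labels_guarded_to_zero(self):
        stats, scores = dispersion_scores([0.3] * 5)
        assert stats.mad_y == 0.0
        assert np.all(scores == 0.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            dispersion_scores([])


class TestSelectNeighborhood:
    def test_rho_zero_reduces_to_nearest_neighbors(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.uniform(0, 1, 20)
        z = rng.normal(size=3)
        cfg = _cfg(N=4, rho=0.0)
        sel = select_neighborhood(X, y, z, cfg)
        kappa = kernel_space_distance(compute_kernel_matrices(X, z[None, :], cfg.kernel))[:, 0]
        expected = np.sort(np.argsort(kappa, kind="stable")[:4])
        np.testing.assert_array_equal(sel.sigma, expected)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 2.0])
    def test_attains_exhaustive_minimum_on_full_pool(self, rng, rho):
        for _ in range(10):
            L = int(rng.integers(6, 13))
            N = int(rng.integers(2, min(5, L)))
            X = rng.normal(size=(L, 3))
            y = rng.uniform(0, 1, L)
            z = rng.normal(size=3)
            cfg = _cfg(N=N, rho=rho, pool_multiplier=12)  # pool covers the whole set
            sel = select_neighborhood(X, y, z, cfg)
            best = exhaustive_selection_minimum(sel.kappa_row, y, N, rho)
            assert sel.objective_value == pytest.approx(best, abs=1e-10)

    def test_label_outlier_at_test_point_is_excluded(self, rng):
        # one example shares the test features but its label is aberrant
        z = rng.normal(size=3)
        X = np.vstack([z, z + rng.normal(0, 0.05, size=(11, 3))])
        y = np.r_[0.9, np.full(11, 0.1)]
        sel = select_neighborhood(X, y, z, _cfg(N=5, rho=5.0))
        assert 0 not in sel.sigma

    def test_omega_consistent_with_sigma(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.uniform(0, 1, 15)
        sel = select_neighborhood(X, y, X[3], _cfg(N=5))
        assert sel.omega.sum() == 5
        np.testing.assert_array_equal(np.flatnonzero(sel.omega), sel.sigma)

    def test_oversized_neighborhood_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="N"):
            select_neighborhood(X, np.zeros(4), X[0], _cfg(N=5))

    def test_deterministic_tie_break_to_lower_index(self):
        X = np.zeros((6, 2))  # all identical: every kappa ties at 0
        y = np.full(6, 0.5)
        sel = select_neighborhood(X, y, np.zeros(2), _cfg(N=3))
        np.testing.assert_array_equal(sel.sigma, [0, 1, 2])

    def test_increasing_rho_never_raises_max_dispersion_in_sigma(self, rng):
        for _ in range(10):
            X = rng.normal(size=(25, 3))
            y = rng.uniform(0, 1, 25)
            z = rng.normal(size=3)
            prev = None
            for rho in (0.0, 0.3, 1.0, 3.0, 10.0):
                sel = select_neighborhood(X, y, z, _cfg(N=5, rho=rho))
                worst = sel.dispersion_terms[sel.sigma].max()
                if prev is not None:
                    assert worst <= prev + 1e-12
                prev = worst


class TestPredictTransductive:
    def test_unanimous_neighborhood_predicts_its_label(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.full(12, 0.7)
        yhat, sel, model = predict_transductive(X, y, X[0], _cfg(N=5, epsilon=0.1))
        assert abs(yhat - 0.7) <= 0.1

    def test_locality_ignores_far_cluster(self, rng):
        a = rng.normal(0, 0.1, size=(20, 2))
        b = rng.normal(10, 0.1, size=(20, 2))
        X = np.vstack([a, b])
        y = np.r_[np.full(20, 0.2), np.full(20, 0.8)]
        yhat, _, _ = predict_transductive(X, y, np.zeros(2), _cfg(N=5))
        assert abs(yhat - 0.2) < 0.1

    def test_equivalent_to_plain_esvr_on_subset(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(0, 1, 30)
        z = rng.normal(size=3)
        cfg = _cfg(N=6)
        yhat, sel, _ = predict_transductive(X, y, z, cfg)
        sub = sel.sigma
        sub_model = fit_weighted_svr(
            X[sub], y[sub], np.ones(6), C=cfg.C, epsilon=cfg.epsilon, kernel=cfg.kernel
        )
        assert yhat == pytest.approx(predict_svr(sub_model, z), abs=1e-8)


class TestLabeledExample:
    def test_label_range_enforced(self):
        with pytest.raises(ValueError):
            LabeledExample(np.zeros(3), 1.2, "S01")


def _homogeneous_frame(n_subjects=1, n_per=64, seed=0, noise=0.02):
    # one well-separated linear label->feature line shared by all subjects,
    # balanced over the eight Stroop levels
    rng = np.random.default_rng(seed)
    slope = rng.normal(0, 1, 4)
    slope = 2 * slope / np.linalg.norm(slope)
    levels = np.arange(8) / 7.0
    rows = []
    for s in range(n_subjects):
        ys = np.tile(levels, n_per // 8 + 1)[:n_per]
        rng.shuffle(ys)
        for y in ys:
            x = slope * y + rng.normal(0, noise, 4)
            rows.append({"subject_id": f"S{s+1:02d}", "y": y, **{f"f{k}": x[k] for k in range(4)}})
    return pd.DataFrame(rows)


class TestRunners:
    def test_st_svr_prediction_bookkeeping(self):
        frame = _homogeneous_frame(1, 50, seed=1)
        report = run_st_svr(frame, "S01", TransductiveConfig(), folds=5, seed=0)
        assert report.n_predictions == 50

    def test_st_svr_accurate_on_homogeneous_subject(self):
        frame = _homogeneous_frame(1, 50, seed=2)
        report = run_st_svr(frame, "S01", TransductiveConfig(), folds=5, seed=0)
        assert report.mae < 0.05

    def test_st_svr_deterministic_given_seed(self):
        frame = _homogeneous_frame(1, 50, seed=3)
        r1 = run_st_svr(frame, "S01", TransductiveConfig(), folds=5, seed=7)
        r2 = run_st_svr(frame, "S01", TransductiveConfig(), folds=5, seed=7)
        assert r1.mae == r2.mae

    def test_st_svr_too_few_examples_names_subject(self):
        frame = _homogeneous_frame(1, 6, seed=4)
        with pytest.raises(ValueError, match="S01"):
            run_st_svr(frame, "S01", TransductiveConfig(), folds=5)

    def test_t_svr_requires_multiple_subjects(self):
        frame = _homogeneous_frame(1, 50, seed=5)
        with pytest.raises(ValueError, match="multi-subject"):
            run_t_svr(frame, "S01", TransductiveConfig(), folds=5)

    def test_t_svr_matches_st_svr_under_shared_map(self):
        # all subjects drawn from one latent map: pooling cannot hurt much
        diffs = []
        for seed in range(10):
            frame = _homogeneous_frame(3, 64, seed=seed)
            st = run_st_svr(frame, "S01", TransductiveConfig(), folds=5, seed=seed)
            t = run_t_svr(frame, "S01", TransductiveConfig(), folds=5, seed=seed)
            diffs.append(abs(st.mae - t.mae))
        assert np.mean(diffs) < 0.02
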