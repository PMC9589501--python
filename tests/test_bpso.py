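"""Binary-PSO wrapper selection: decoding, fitness, swarm dynamics, consensus."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from stressfeat import (
    BpsoFeatureSelector,
    FeatureMatrix,
    SwarmConfig,
    consensus_features,
    decode_solution,
    fitness,
    fitness_value,
    run_bpso,
)
from stressfeat.bpso import HoldoutKnnEvaluator, init_swarm, step_swarm
from stressfeat.errors import ValidationError


class TestDecode:
    def test_worked_example(self):
        position = np.array([0.82, 0.63, 0.35, 0, 0, 1, 0.98, 0.87, 0.14])
        mask = decode_solution(position)
        np.testing.assert_array_equal(np.flatnonzero(mask), [0, 1, 5, 6, 7])

    def test_all_zeros_empty_mask(self):
        assert not decode_solution(np.zeros(12)).any()

    def test_half_is_selected(self):
        assert decode_solution(np.array([0.5])).all()

    def test_matches_threshold_oracle(self, rng):
        x = rng.uniform(size=(10_000, 12))
        for row in x:
            np.testing.assert_array_equal(decode_solution(row), row >= 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            decode_solution(np.array([0.5, 1.2]))


class TestFitnessValue:
    def test_closed_forms(self):
        assert fitness_value(0.0, 12, 12).value == pytest.approx(0.1, abs=1e-12)
        assert fitness_value(0.25, 3, 12).value == pytest.approx(0.25, abs=1e-12)

    def test_empty_mask_worst(self):
        assert fitness_value(0.37, 0, 12).value == 1.0

    def test_identity_invariant(self, rng):
        for _ in range(100):
            er = rng.uniform()
            k = int(rng.integers(1, 13))
            fv = fitness_value(er, k, 12)
            assert fv.value == pytest.approx(0.9 * er + 0.1 * k / 12, abs=1e-12)

    def test_parsimony_pressure(self):
        """Equal error rates: the smaller subset has strictly lower fitness."""
        assert fitness_value(0.2, 3, 12).value < fitness_value(0.2, 7, 12).value


def _toy_matrix(n_per_class=40, d=3, informative=0, shift=4.0, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(size=(n_per_class, d))
    Xb = rng.normal(size=(n_per_class, d))
    Xb[:, informative] += shift
    X = pd.DataFrame(np.vstack([Xa, Xb]), columns=[f"f{i}" for i in range(d)])
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return FeatureMatrix(X, y)


class TestEvaluator:
    def test_fitness_op_uses_knn_holdout(self):
        fm = _toy_matrix()
        cfg = SwarmConfig(dimensions=3, seed=0)
        fv = fitness(np.array([True, False, False]), fm, cfg)
        assert fv.error_rate <= 0.1  # well-separated informative feature
        assert fv.n_selected == 1 and fv.n_total == 3

    def test_empty_mask_convention(self):
        fm = _toy_matrix()
        fv = fitness(np.zeros(3, bool), fm, SwarmConfig(dimensions=3, seed=0))
        assert fv.value == 1.0

    def test_matches_sklearn_knn(self):
        """Independent route: sklearn KNN on the same split and scaling."""
        fm = _toy_matrix(n_per_class=60, d=4, shift=1.0, seed=3)
        cfg = SwarmConfig(dimensions=4, seed=9)
        ev = HoldoutKnnEvaluator(fm, cfg)
        mask = np.array([True, True, False, True])
        X = fm.X.to_numpy(float)
        tr, te = ev._train, ev._test
        mu, sd = X[tr].mean(0), X[tr].std(0)
        Z = (X - mu) / np.where(sd == 0, 1.0, sd)
        clf = KNeighborsClassifier(n_neighbors=5)
        clf.fit(Z[tr][:, mask], fm.y[tr])
        sk_err = float(np.mean(clf.predict(Z[te][:, mask]) != fm.y[te]))
        assert ev.error_rate(mask) == pytest.approx(sk_err, abs=1e-12)

    def test_too_small_class_rejected(self):
        X = pd.DataFrame({"f0": [0.0, 1.0]})
        fm = FeatureMatrix(X, np.array(["A", "B"]))
        with pytest.raises(ValidationError):
            HoldoutKnnEvaluator(fm, SwarmConfig(dimensions=1, seed=0))


class TestSwarmDynamics:
    def test_init_reproducible_and_bounded(self):
        cfg = SwarmConfig(dimensions=4, n_particles=10, seed=5)
        ev = lambda p: float(np.sum(p))
        s1, s2 = init_swarm(cfg, ev), init_swarm(cfg, ev)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        assert np.all((s1.positions >= 0) & (s1.positions <= 1))
        assert np.all(np.abs(s1.velocities) <= cfg.velocity_clamp)

    def test_init_scalar_dimension(self):
        cfg = SwarmConfig(dimensions=1, n_particles=5, seed=0)
        s = init_swarm(cfg, lambda p: 0.0)
        assert s.positions.shape == (5, 1)

    def test_init_positions_uniform_mean(self):
        cfg = SwarmConfig(dimensions=3, n_particles=1000, seed=2)
        s = init_swarm(cfg, lambda p: 0.0)
        means = s.positions.mean(axis=0)
        assert np.all((means > 0.45) & (means < 0.55))

    def test_fixed_point_when_converged(self):
        cfg = SwarmConfig(dimensions=2, n_particles=4, seed=1)
        ev = lambda p: float(np.abs(p - 0.5).sum())
        swarm = init_swarm(cfg, ev)
        target = swarm.gbest_position.copy()
        swarm.positions[:] = target
        swarm.pbest_positions[:] = target
        swarm.velocities[:] = 0.0
        step_swarm(swarm, ev)
        np.testing.assert_array_equal(swarm.positions, np.tile(target, (4, 1)))

    def test_gbest_trace_nonincreasing(self):
        fm = _toy_matrix(shift=1.0)
        run = run_bpso(fm, SwarmConfig(dimensions=3, iterations=40, seed=7))
        assert np.all(np.diff(run.trace) <= 0)
        assert run.trace.size == 41

    def test_one_dimensional_surrogate_convergence(self):
        """Gbest finds the minimum of |x - 0.7| within 0.05 in >= 18/20 seeds."""
        hits = 0
        for seed in range(20):
            cfg = SwarmConfig(dimensions=1, n_particles=20, iterations=100, seed=seed)
            ev = lambda p: float(abs(p[0] - 0.7))
            swarm = init_swarm(cfg, ev)
            for _ in range(cfg.iterations):
                step_swarm(swarm, ev)
            hits += abs(swarm.gbest_position[0] - 0.7) < 0.05
        assert hits >= 18


class TestRunBpso:
    def test_single_informative_dimension_selected(self):
        fm = _toy_matrix(d=1)
        run = run_bpso(fm, SwarmConfig(dimensions=1, iterations=20, seed=0))
        assert run.mask.tolist() == [True]

    def test_deterministic_given_seed(self):
        fm = _toy_matrix(shift=1.5)
        cfg = SwarmConfig(dimensions=3, iterations=30, seed=4)
        r1, r2 = run_bpso(fm, cfg), run_bpso(fm, cfg)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_informative_feature_recovered(self):
        fm = _toy_matrix(d=6, informative=2, shift=3.0, seed=5)
        run = run_bpso(fm, SwarmConfig(dimensions=6, iterations=60, seed=1))
        assert run.mask[2]


class TestConsensus:
    def test_identical_masks(self):
        mask = np.zeros(12, bool)
        mask[[2, 5, 9]] = True
        res = consensus_features([mask] * 20, [f"b{i}" for i in range(12)])
        assert set(res.consensus) == {"b2", "b5", "b9"}
        assert all(res.counts[[2, 5, 9]] == 20)

    def test_counts_match_column_sum_oracle(self, rng):
        masks = rng.uniform(size=(20, 8)) > 0.5
        res = consensus_features(list(masks), [f"b{i}" for i in range(8)])
        np.testing.assert_array_equal(res.counts, masks.sum(axis=0))

    def test_three_features_always_full_consensus(self, rng):
        masks = rng.uniform(size=(5, 3)) > 0.5
        res = consensus_features(list(masks), ["x", "y", "z"])
        assert set(res.consensus) == {"x", "y", "z"}

    def test_tie_break_by_magnitude_then_label(self):
        masks = [np.array([True, True, True, False])] * 4
        res = consensus_features(
            masks, ["a", "b", "c", "d"], magnitudes=np.array([1.0, 3.0, 2.0, 9.0])
        )
        assert res.consensus == ("b", "c", "a")

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            consensus_features([], ["a"])


class TestNullConsensus:
    def test_counts_near_uniform_on_uninformative_data(self):
        """On iid-noise features (nothing to select) the 20-seed consensus
        counts stay near-uniform: no feature is systematically preferred."""
        for ms in range(5):
            rng = np.random.default_rng(600 + ms)
            X = pd.DataFrame(
                rng.normal(size=(400, 12)), columns=[f"b{i}" for i in range(12)]
            )
            fm = FeatureMatrix(X, np.array(["A"] * 200 + ["B"] * 200))
            masks = [
                run_bpso(fm, SwarmConfig(dimensions=12, seed=4000 + 100 * ms + s)).mask
                for s in range(20)
            ]
            res = consensus_features(masks, list(fm.bone_labels))
            assert res.counts.max() - res.counts.min() <= 10


class TestSelectorEstimator:
    def test_sklearn_interface(self):
        fm = _toy_matrix(n_per_class=40, d=5, informative=1, shift=3.0, seed=2)
        sel = BpsoFeatureSelector(n_seeds=3, iterations=20, random_state=0)
        sel.fit(fm.X, fm.y)
        assert sel.support_.sum() == 3
        assert sel.masks_.shape == (3, 5)
        assert "f1" in sel.consensus_labels_
        assert sel.transform(fm.X).shape == (80, 3)
        params = sel.get_params()
        assert params["n_seeds"] == 3
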