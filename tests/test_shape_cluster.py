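"""Fréchet distance, senator/timepoint reduction, and shape k-means."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from beatshape.shape_cluster import (
    ClusterConfig,
    ClusterModel,
    assign_all,
    fit_kmlshape,
    frechet_distance,
    reduce_senators,
    reduce_times,
)
from conftest import brute_frechet


class TestFrechetDistance:
    def test_identical_trajectories_zero(self):
        a = np.column_stack([np.arange(10), np.sin(np.arange(10))])
        assert frechet_distance(a, a) == 0.0

    def test_parallel_unit_offset_segments(self):
        a = np.array([(0.0, 0.0), (1.0, 0.0)])
        b = np.array([(0.0, 1.0), (1.0, 1.0)])
        assert frechet_distance(a, b, timescale=1.0) == 1.0

    def test_matches_brute_force_recursion(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = rng.normal(size=(rng.integers(1, 9), 2))
            b = rng.normal(size=(rng.integers(1, 9), 2))
            assert frechet_distance(a, b, 1.0) == pytest.approx(
                brute_frechet(a, b), abs=1e-12
            )

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c = (rng.normal(size=(6, 2)) for _ in range(3))
            dab = frechet_distance(a, b, 1.0)
            dba = frechet_distance(b, a, 1.0)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= frechet_distance(a, c, 1.0) + frechet_distance(c, b, 1.0) + 1e-12

    def test_empty_or_missing_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(np.empty((0, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            frechet_distance(np.array([1.0, np.nan]), np.array([1.0, 2.0]))


class TestSenatorReduction:
    def test_identity_when_senators_cover_beats(self):
        X = np.random.default_rng(0).normal(size=(20, 15))
        sens, w, mapping = reduce_senators(X, 25)
        assert np.array_equal(sens, X)
        assert np.all(w == 1.0)
        assert np.array_equal(mapping, np.arange(20))

    def test_two_family_fixture_recovers_groups(self):
        rng = np.random.default_rng(1)
        fam_a = rng.normal(0.0, 0.05, size=(30, 10))
        fam_b = rng.normal(5.0, 0.05, size=(50, 10))
        X = np.vstack([fam_a, fam_b])
        sens, w, mapping = reduce_senators(X, 2, seed=0)
        order = np.argsort(sens[:, 0])
        assert sorted(w.tolist()) == [30.0, 50.0]
        lo, hi = sens[order[0]], sens[order[1]]
        assert np.all((lo > fam_a.min(axis=0) - 1e-9) & (lo < fam_a.max(axis=0) + 1e-9))
        assert np.all((hi > fam_b.min(axis=0) - 1e-9) & (hi < fam_b.max(axis=0) + 1e-9))

    def test_weights_conserve_beat_count(self):
        X = np.random.default_rng(2).normal(size=(123, 8))
        for s in (5, 20, 123, 200):
            _, w, mapping = reduce_senators(X, s, seed=1)
            assert w.sum() == 123
            assert len(mapping) == 123

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            reduce_senators(np.ones((5, 3)), 0)


class TestTimeReduction:
    def test_none_is_identity(self):
        X = np.random.default_rng(0).normal(size=(4, 20))
        out, times = reduce_times(X, None)
        assert np.array_equal(out, X)

    def test_linear_ramp_resampled_exactly(self):
        X = np.linspace(0.0, 1.0, 150)[None, :].repeat(3, axis=0)
        for t in (100, 17, 2):
            out, _ = reduce_times(X, t)
            expected = np.linspace(0.0, 1.0, t)
            assert np.max(np.abs(out - expected)) < 1e-9

    def test_length_and_endpoints(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 150))
        out, times = reduce_times(X, 100)
        assert out.shape == (6, 100)
        assert np.allclose(out[:, 0], X[:, 0]) and np.allclose(out[:, -1], X[:, -1])

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            reduce_times(np.ones((2, 10)), 1)


class TestKmlShapeFit:
    def test_k_equals_s_converges_in_one_iteration(self):
        X = np.random.default_rng(0).normal(size=(8, 12))
        model = fit_kmlshape(X, np.ones(8), ClusterConfig(8, 8, seed=0))
        assert model.converged and model.n_iter == 1
        assert sorted(model.senator_labels.tolist()) == list(range(1, 9))

    def test_three_family_fixture_perfect_recovery(self, three_family_fixture):
        X, times, y = three_family_fixture
        sens, w, mapping = reduce_senators(X, 60, seed=0)
        model = fit_kmlshape(sens, w, ClusterConfig(60, 3, seed=0), times)
        labels = assign_all(mapping, model)
        assert model.converged
        assert adjusted_rand_score(y, labels) == 1.0

    def test_same_seed_reproduces_model(self):
        X = np.random.default_rng(1).normal(size=(30, 10))
        w = np.ones(30)
        m1 = fit_kmlshape(X, w, ClusterConfig(30, 4, seed=9))
        m2 = fit_kmlshape(X, w, ClusterConfig(30, 4, seed=9))
        assert np.array_equal(m1.senator_labels, m2.senator_labels)
        assert np.array_equal(m1.centers, m2.centers)

    def test_assignment_step_never_increases_cost(self, three_family_fixture):
        X, times, _ = three_family_fixture
        sens, w, _ = reduce_senators(X, 40, seed=2)
        model = fit_kmlshape(sens, w, ClusterConfig(40, 4, seed=2), times)
        for before, after in model.cost_history:
            assert after <= before + 1e-9

    def test_cluster_ids_ordered_by_weight(self, three_family_fixture):
        X, times, _ = three_family_fixture
        sens, w, _ = reduce_senators(X, 50, seed=0)
        model = fit_kmlshape(sens, w, ClusterConfig(50, 3, seed=0), times)
        totals = [w[model.senator_labels == k].sum() for k in (1, 2, 3)]
        assert totals == sorted(totals, reverse=True)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            ClusterConfig(3, 5)

    def test_model_json_roundtrip(self, tmp_path):
        X = np.random.default_rng(4).normal(size=(10, 6))
        model = fit_kmlshape(X, np.ones(10), ClusterConfig(10, 2, seed=1))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ClusterModel.from_json(path)
        assert np.allclose(loaded.centers, model.centers)
        assert np.array_equal(loaded.senator_labels, model.senator_labels)
        assert loaded.config == model.config


class TestAssignAll:
    def test_identity_senators_match_direct_assignment(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 5)), rng.normal(4, 0.1, (10, 5))])
        sens, w, mapping = reduce_senators(X, 25)
        model = fit_kmlshape(sens, w, ClusterConfig(25, 2, seed=0))
        labels = assign_all(mapping, model)
        tx = model.timescale * model.times
        direct = np.array(
            [
                1
                + np.argmin(
                    [
                        frechet_distance(
                            np.column_stack([model.times, x]),
                            np.column_stack([model.times, c]),
                            model.timescale,
                        )
                        for c in model.centers
                    ]
                )
                for x in X
            ]
        )
        assert np.array_equal(labels, direct)

    def test_label_counts_equal_summed_weights(self, three_family_fixture):
        X, times, _ = three_family_fixture
        sens, w, mapping = reduce_senators(X, 50, seed=3)
        model = fit_kmlshape(sens, w, ClusterConfig(50, 3, seed=3), times)
        labels = assign_all(mapping, model)
        assert len(labels) == len(X)
        for k in (1, 2, 3):
            assert (labels == k).sum() == w[model.senator_labels == k].sum()

    def test_unknown_senator_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        model = fit_kmlshape(X, np.ones(5), ClusterConfig(5, 2, seed=0))
        with pytest.raises(ValueError):
            assign_all(np.array([0, 9]), model)
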