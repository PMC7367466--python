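import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rangeshift import (
    ALGORITHMS,
    Grid,
    GridSpec,
    OccurrenceSet,
    SuitabilityMap,
    ModelScore,
    bootstrap_partitions,
    build_ensemble,
    cumulative_distance_layer,
    ensemble,
    fit_model,
    sample_pseudo_absences,
    select_threshold,
    sorensen_index,
)
from rangeshift.sdm import TrainingSet
from oracles import best_threshold_sweep, sorensen_set_form, summed_distance_double_loop


def occ_of(points):
    return OccurrenceSet(taxon_id="t", points=np.asarray(points, dtype=float))


class TestPseudoAbsences:
    def test_count_equals_presences_and_disjoint(self, spec10):
        rng = np.random.default_rng(0)
        occ = occ_of(rng.uniform(0, 10, (10, 2)))
        absences = sample_pseudo_absences(occ, spec10, seed=1)
        assert len(absences) == len(occ)
        pres_cells = {tuple(c) for c in spec10.cells_of(occ.points)}
        abs_cells = {tuple(c) for c in spec10.cells_of(absences)}
        assert pres_cells.isdisjoint(abs_cells)
        assert len(abs_cells) == len(absences)  # without replacement

    def test_forced_outcome_when_k_cells_remain(self):
        spec = GridSpec(2, 3)
        centers = spec.all_centers()
        occ = occ_of(centers[:3])
        absences = sample_pseudo_absences(occ, spec, seed=0)
        assert {tuple(p) for p in absences} == {tuple(p) for p in centers[3:]}

    def test_insufficient_cells_rejected(self):
        spec = GridSpec(2, 2)
        occ = occ_of(spec.all_centers()[:3])
        with pytest.raises(ValueError, match="presence-free"):
            sample_pseudo_absences(occ, spec, seed=0)

    def test_selection_uniform_over_seeds(self):
        """Monte-Carlo: per-cell selection frequency consistent with uniform
        sampling (99% binomial bounds)."""
        spec = GridSpec(4, 4)
        occ = occ_of(spec.all_centers()[:4])
        n_empty, k = 12, 4
        hits = np.zeros(spec.n_cells)
        n_seeds = 1000
        for s in range(n_seeds):
            pts = sample_pseudo_absences(occ, spec, seed=s)
            cells = spec.cells_of(pts)
            hits[cells[:, 0] * 4 + cells[:, 1]] += 1
        p = k / n_empty
        se = np.sqrt(p * (1 - p) / n_seeds)
        freq = hits[4:] / n_seeds
        assert np.all(np.abs(freq - p) < 2.58 * se + 1e-9)


class TestPartitions:
    def test_seventy_thirty_split(self):
        rng = np.random.default_rng(1)
        parts = bootstrap_partitions(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)), seed=0)
        assert len(parts) == 5
        assert [p.partition_id for p in parts] == [1, 2, 3, 4, 5]
        for p in parts:
            assert (p.y_train == 1).sum() == 7 and (p.y_test == 1).sum() == 3
            assert (p.y_train == 0).sum() == 7 and (p.y_test == 0).sum() == 3

    def test_train_test_partition_property(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(9, 2))
        A = rng.normal(size=(9, 2))
        for p in bootstrap_partitions(P, A, seed=3):
            got = np.vstack([p.X_train[p.y_train == 1], p.X_test[p.y_test == 1]])
            assert np.array_equal(np.sort(got, axis=0), np.sort(P, axis=0))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_partitions(np.zeros((1, 2)), np.ones((5, 2)))


class TestFitModel:
    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_separable_case_perfect_at_half_threshold(self, alg):
        rng = np.random.default_rng(4)
        x_pres = rng.uniform(2.0, 3.0, 20)[:, None]
        x_abs = rng.uniform(-3.0, -2.0, 20)[:, None]
        parts = bootstrap_partitions(x_pres, x_abs, seed=0, feature_names=["x"])
        bg = rng.uniform(-3.5, 3.5, 300)[:, None]
        part = parts[0]
        fit = fit_model(alg, part, background=bg, seed=0)
        pred = fit.predict(part.X_test) >= 0.5
        assert np.array_equal(pred, part.y_test.astype(bool))

    def test_predictions_bounded(self):
        rng = np.random.default_rng(5)
        P, A = rng.normal(1, 1, (15, 3)), rng.normal(-1, 1, (15, 3))
        part = bootstrap_partitions(P, A, seed=0)[0]
        bg = rng.normal(0, 2, (200, 3))
        for alg in ALGORITHMS:
            p = fit_model(alg, part, background=bg, seed=0).predict(bg)
            assert np.all((p >= 0) & (p <= 1))

    def test_single_class_rejected_for_presence_absence(self):
        X = np.random.default_rng(6).normal(size=(10, 2))
        part = TrainingSet(X, np.ones(10, dtype=int), X[:2], np.ones(2, dtype=int), 1, ["a", "b"])
        for alg in ("margin_classifier", "tree_bag"):
            with pytest.raises(ValueError, match="both classes"):
                fit_model(alg, part, seed=0)

    def test_shuffled_labels_score_near_no_skill(self):
        """Label permutation: mean test Sørensen across replicates sits near
        the prevalence-expected no-skill value (all-positive prediction on a
        balanced fold gives 2p/(1+p) = 2/3)."""
        rng = np.random.default_rng(7)
        from rangeshift import score_fit

        vals = []
        for rep in range(20):
            X = rng.standard_normal((30, 3))
            y = np.array([1] * 15 + [0] * 15)
            rng.shuffle(y)
            P, A = X[y == 1], X[y == 0]
            part = bootstrap_partitions(P, A, n_reps=1, seed=rep)[0]
            fit = fit_model("tree_bag", part, seed=rep)
            vals.append(score_fit(fit, part.X_test, part.y_test).sorensen)
        assert abs(np.mean(vals) - 2 / 3) < 0.15


class TestSorensen:
    def test_direct_values(self):
        assert sorensen_index([1, 1, 0], [1, 1, 0]) == 1.0
        # TP=3, FP=1, FN=1 -> 6/8
        assert sorensen_index([1, 1, 1, 1, 0], [1, 1, 1, 0, 1]) == pytest.approx(0.75)
        assert sorensen_index([0, 0, 0], [0, 1, 0]) == 0.0

    def test_no_observed_positives_rejected(self):
        with pytest.raises(ValueError, match="positives"):
            sorensen_index([1, 0], [0, 0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1).filter(
        lambda v: any(o for _, o in v)
    ))
    def test_agrees_with_set_form(self, pairs):
        pred = [p for p, _ in pairs]
        obs = [o for _, o in pairs]
        if not (any(pred) or any(obs)):
            return
        assert sorensen_index(pred, obs) == pytest.approx(sorensen_set_form(pred, obs))


class TestSelectThreshold:
    def test_scores_equal_labels(self):
        y = np.array([1, 0, 1, 0, 1], dtype=bool)
        ms = select_threshold(y.astype(float), y)
        assert ms.sorensen == 1.0
        assert ms.threshold_used == 1.0  # largest candidate wins the tie

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            scores = rng.random(25)
            obs = rng.random(25) > 0.6
            if not obs.any():
                obs[0] = True
            ms = select_threshold(scores, obs)
            val, t = best_threshold_sweep(scores, obs)
            assert ms.sorensen == pytest.approx(val)
            assert ms.threshold_used == pytest.approx(t)

    def test_monotone_transform_preserves_partition(self):
        rng = np.random.default_rng(9)
        scores = rng.random(30)
        obs = rng.random(30) > 0.5
        obs[0] = True
        a = select_threshold(scores, obs)
        b = select_threshold(scores**3, obs)
        assert a.sorensen == pytest.approx(b.sorensen)
        assert np.array_equal(scores >= a.threshold_used, scores**3 >= b.threshold_used)


class TestEnsemble:
    def _map(self, spec, data):
        return SuitabilityMap(grid=Grid(spec, np.asarray(data, dtype=float)))

    def test_identical_members_fixed_point(self, spec10):
        data = np.random.default_rng(10).random((10, 10))
        maps = [self._map(spec10, data) for _ in range(3)]
        scores = [ModelScore(0.7, 0.5), ModelScore(0.8, 0.5), ModelScore(0.9, 0.5)]
        out = ensemble(maps, scores)
        assert np.allclose(out.grid.data, data)

    def test_below_mean_member_excluded(self, spec10):
        a = self._map(spec10, np.zeros((10, 10)))
        b = self._map(spec10, np.zeros((10, 10)))
        c = self._map(spec10, np.ones((10, 10)))
        out = ensemble([a, b, c], [ModelScore(0.9, 0.5), ModelScore(0.9, 0.5), ModelScore(0.2, 0.5)])
        # mean score ~0.667: only the two 0.9 members (both zero maps) remain
        assert np.allclose(out.grid.data, 0.0)

    def test_all_equal_scores_includes_everyone(self, spec10):
        a = self._map(spec10, np.zeros((10, 10)))
        b = self._map(spec10, np.ones((10, 10)))
        out = ensemble([a, b], [ModelScore(0.5, 0.5), ModelScore(0.5, 0.5)])
        assert np.allclose(out.grid.data, 0.5)

    def test_convex_combination_bounds(self, spec10):
        rng = np.random.default_rng(11)
        maps = [self._map(spec10, rng.random((10, 10))) for _ in range(4)]
        scores = [ModelScore(s, 0.5) for s in (0.6, 0.7, 0.8, 0.9)]
        out = ensemble(maps, scores)
        included = [m.grid.data for m, s in zip(maps, scores) if s.sorensen > 0.75 - 1e-9]
        lo = np.min(included, axis=0)
        hi = np.max(included, axis=0)
        assert np.all(out.grid.data >= lo - 1e-12)
        assert np.all(out.grid.data <= hi + 1e-12)

    def test_geometry_mismatch_rejected(self, spec10, spec20):
        a = self._map(spec10, np.zeros((10, 10)))
        b = SuitabilityMap(grid=Grid(spec20, np.zeros((20, 20))))
        with pytest.raises(ValueError, match="geometry"):
            ensemble([a, b], [ModelScore(0.5, 0.5), ModelScore(0.5, 0.5)])


class TestCumulativeDistance:
    def test_single_occurrence_radial_cone(self):
        spec = GridSpec(9, 9)
        occ = occ_of([spec.cell_center(4, 4)])
        layer = cumulative_distance_layer(occ, spec)
        assert layer.grid.data[4, 4] == 0.0
        assert layer.grid.data.max() == 1.0
        # radially symmetric: the four corners tie
        corners = [layer.grid.data[i, j] for i in (0, 8) for j in (0, 8)]
        assert np.allclose(corners, corners[0])

    def test_two_occurrences_mirror_symmetry(self):
        spec = GridSpec(10, 10)
        occ = occ_of([spec.cell_center(4, 2), spec.cell_center(4, 7)])
        data = cumulative_distance_layer(occ, spec).grid.data
        assert np.allclose(data, data[:, ::-1], atol=1e-12)

    def test_matches_double_loop_oracle(self):
        spec = GridSpec(15, 15)
        rng = np.random.default_rng(12)
        occ = occ_of(rng.uniform(0, 15, (6, 2)))
        layer = cumulative_distance_layer(occ, spec)
        raw = summed_distance_double_loop(spec.all_centers(), occ.points)
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.max(np.abs(layer.grid.data.ravel() - norm)) < 1e-9

    def test_empty_occurrences_rejected(self, spec10):
        with pytest.raises(ValueError):
            cumulative_distance_layer(occ_of(np.empty((0, 2))), spec10)
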