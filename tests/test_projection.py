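import numpy as np
import pytest

from rangeshift import (
    Grid,
    GridSpec,
    OccurrenceSet,
    ScenarioSpec,
    SuitabilityMap,
    apply_dispersal,
    apply_forest_mask,
    binarize,
    bootstrap_partitions,
    build_ensemble,
    cumulative_distance_layer,
    fit_model,
    gcm_consensus,
    make_climate_stack,
    make_forest_masks,
    niche_from_stack,
    perturb_to_future,
    project,
    sample_occurrences,
    sample_pseudo_absences,
    score_fit,
    true_suitability,
)
from rangeshift import sdm


@pytest.fixture(scope="module")
def small_world():
    spec = GridSpec(20, 20)
    stack = make_climate_stack(spec, seed=2)
    truth = true_suitability(niche_from_stack(stack, seed=2), stack)
    occ = sample_occurrences(truth, 25, seed=2)
    absences = sample_pseudo_absences(occ, spec, seed=2)
    names = stack.layer_names
    cp, ca = spec.cells_of(occ.points), spec.cells_of(absences)
    Xp = np.column_stack([stack.layers[v][cp[:, 0], cp[:, 1]] for v in names])
    Xa = np.column_stack([stack.layers[v][ca[:, 0], ca[:, 1]] for v in names])
    parts = bootstrap_partitions(Xp, Xa, seed=2, feature_names=names)
    bg = stack.as_matrix(names)
    fits, scores = [], []
    for part in parts[:2]:
        for alg in ("maxent_like", "tree_bag"):
            f = fit_model(alg, part, background=bg, seed=2)
            fits.append(f)
            scores.append(score_fit(f, part.X_test, part.y_test))
    ens = build_ensemble(fits, scores)
    return spec, stack, occ, ens


class TestProject:
    def test_training_climate_reproduces_predictions(self, small_world):
        spec, stack, occ, ens = small_world
        smap = project(ens, stack)
        direct = ens.predict(stack.as_matrix(ens.feature_names))
        assert np.max(np.abs(smap.grid.data.ravel() - direct)) < 1e-12

    def test_zero_perturbation_future_identical(self, small_world):
        spec, stack, occ, ens = small_world
        zeros = {v: 0.0 for v in stack.layer_names}
        fut = perturb_to_future(
            stack, "rcp45", 1, delta_mean=zeros, delta_spread=zeros,
            anomaly_amplitude=zeros, seed=0,
        )[0]
        assert np.allclose(project(ens, stack).grid.data, project(ens, fut).grid.data)

    def test_missing_layer_named(self, small_world):
        spec, stack, occ, ens = small_world
        from rangeshift import ClimateStack

        partial = ClimateStack(
            spec=spec, layers={k: v for k, v in stack.layers.items() if k != "bio12"}
        )
        with pytest.raises(KeyError, match="bio12"):
            project(ens, partial)

    def test_dispersal_layer_contract(self, small_world):
        spec, stack, occ, ens = small_world
        layer = cumulative_distance_layer(occ, spec)
        with pytest.raises(ValueError, match="without a dispersal layer"):
            project(ens, stack, dispersal_layer=layer)

    def test_warming_beyond_niche_width_shrinks_range(self):
        """Shift every layer far past the niche breadth: the suitable-cell
        count at a fixed threshold must not increase."""
        spec = GridSpec(20, 20)
        stack = make_climate_stack(spec, seed=5)
        niche = niche_from_stack(stack, seed=5)
        truth = sw_truth = true_suitability(niche, stack)
        occ = sample_occurrences(truth, 30, seed=5)
        absences = sample_pseudo_absences(occ, spec, seed=5)
        names = stack.layer_names
        cp, ca = spec.cells_of(occ.points), spec.cells_of(absences)
        Xp = np.column_stack([stack.layers[v][cp[:, 0], cp[:, 1]] for v in names])
        Xa = np.column_stack([stack.layers[v][ca[:, 0], ca[:, 1]] for v in names])
        parts = bootstrap_partitions(Xp, Xa, seed=5, feature_names=names)
        fit = fit_model("maxent_like", parts[0], background=stack.as_matrix(names), seed=5)
        sds = {v: stack.layers[v].std() for v in names}
        big = {v: 6.0 * sds[v] for v in names}  # >> niche breadth of 1.5 sd
        zeros = {v: 0.0 for v in names}
        fut = perturb_to_future(stack, "rcp85", 1, delta_mean=big,
                                delta_spread=zeros, anomaly_amplitude=zeros, seed=0)[0]
        cur = project(fit, stack)
        shifted = project(fit, fut)
        thr = 0.5
        assert binarize(shifted, thr).suitable_cell_count <= binarize(cur, thr).suitable_cell_count


class TestConsensus:
    def _map(self, spec, data):
        return SuitabilityMap(grid=Grid(spec, np.asarray(data, dtype=float)))

    def test_identical_realizations(self, spec10):
        data = np.random.default_rng(0).random((10, 10))
        out = gcm_consensus([self._map(spec10, data)] * 3)
        assert np.allclose(out.grid.data, data)

    def test_cellwise_mean_and_bounds(self, spec10):
        a = self._map(spec10, np.full((10, 10), 0.2))
        b = self._map(spec10, np.full((10, 10), 0.6))
        out = gcm_consensus([a, b])
        assert np.allclose(out.grid.data, 0.4)
        rng = np.random.default_rng(1)
        maps = [self._map(spec10, rng.random((10, 10))) for _ in range(5)]
        cons = gcm_consensus(maps)
        stackd = np.stack([m.grid.data for m in maps])
        assert np.all(cons.grid.data >= stackd.min(0) - 1e-12)
        assert np.all(cons.grid.data <= stackd.max(0) + 1e-12)


class TestBinarize:
    def test_threshold_extremes_and_count(self, spec10):
        rng = np.random.default_rng(3)
        data = rng.random((10, 10)) * 0.9
        smap = SuitabilityMap(grid=Grid(spec10, data))
        assert binarize(smap, 0.0).suitable_cell_count == 100
        assert binarize(smap, 1.0).suitable_cell_count == 0
        brm = binarize(smap, 0.5)
        assert brm.suitable_cell_count == int(sum(v >= 0.5 for v in data.ravel()))


class TestDispersalAndMasks:
    def _brm(self, spec, data, **kw):
        return binarize(SuitabilityMap(grid=Grid(spec, data.astype(float))), 0.5, **kw)

    def test_none_mode_is_intersection(self, spec10):
        rng = np.random.default_rng(4)
        cur = self._brm(spec10, rng.random((10, 10)))
        fut = self._brm(spec10, rng.random((10, 10)))
        out = apply_dispersal(cur, fut, "none")
        assert np.array_equal(out.grid.data, cur.grid.data & fut.grid.data)
        assert out.suitable_cell_count <= cur.suitable_cell_count
        same = apply_dispersal(cur, cur, "none")
        assert np.array_equal(same.grid.data, cur.grid.data)

    def test_unlimited_passthrough_and_limited_guard(self, spec10):
        rng = np.random.default_rng(5)
        cur = self._brm(spec10, rng.random((10, 10)))
        fut = self._brm(spec10, rng.random((10, 10)))
        assert apply_dispersal(cur, fut, "unlimited") is fut
        with pytest.raises(ValueError, match="dispersal-constrained"):
            apply_dispersal(cur, fut, "limited")
        ok = self._brm(spec10, rng.random((10, 10)), from_dispersal_fit=True)
        assert apply_dispersal(cur, ok, "limited") is ok

    def test_forest_mask_overlay(self, spec20):
        rng = np.random.default_rng(6)
        brm = self._brm(spec20, rng.random((20, 20)))
        full = Grid(spec20, np.ones((20, 20), dtype=bool))
        empty = Grid(spec20, np.zeros((20, 20), dtype=bool))
        assert np.array_equal(apply_forest_mask(brm, full).grid.data, brm.grid.data)
        assert apply_forest_mask(brm, empty).suitable_cell_count == 0
        masks = make_forest_masks(spec20, 0.6, 0.4, 0.2, seed=1)
        n_bau = apply_forest_mask(brm, masks.bau_2050).suitable_cell_count
        n_gov = apply_forest_mask(brm, masks.gov_2050).suitable_cell_count
        assert n_bau <= n_gov <= brm.suitable_cell_count

    def test_masking_and_dispersal_commute(self, spec10):
        rng = np.random.default_rng(7)
        cur = self._brm(spec10, rng.random((10, 10)))
        fut = self._brm(spec10, rng.random((10, 10)))
        mask = Grid(spec10, rng.random((10, 10)) > 0.4)
        a = apply_forest_mask(apply_dispersal(cur, fut, "none"), mask)
        b = apply_dispersal(cur, apply_forest_mask(fut, mask), "none")
        assert np.array_equal(a.grid.data, b.grid.data)


def test_dispersal_fit_suppresses_far_cells_on_average():
    """Fits that include the cumulative-distance predictor predict lower
    suitability than unconstrained fits in the farthest-distance decile of
    cells, averaged over seeds."""
    from rangeshift.occurrences import deduplicate_per_pixel

    diffs = []
    for seed in (1, 2, 3):
        spec = GridSpec(20, 20)
        stack = make_climate_stack(spec, seed=seed)
        truth = true_suitability(niche_from_stack(stack, seed=seed), stack)
        occ = deduplicate_per_pixel(sample_occurrences(truth, 25, seed=seed), spec)
        absences = sample_pseudo_absences(occ, spec, seed=seed)
        disp = cumulative_distance_layer(occ, spec)
        names = stack.layer_names
        cp, ca = spec.cells_of(occ.points), spec.cells_of(absences)

        def feats(cells, use_d):
            cols = [stack.layers[v][cells[:, 0], cells[:, 1]] for v in names]
            if use_d:
                cols.append(disp.grid.data[cells[:, 0], cells[:, 1]])
            return np.column_stack(cols)

        surfaces = {}
        for use_d in (False, True):
            bg = stack.as_matrix(names)
            if use_d:
                bg = np.column_stack([bg, disp.grid.data.ravel()])
            fn = names + (["cumdist"] if use_d else [])
            parts = bootstrap_partitions(
                feats(cp, use_d), feats(ca, use_d), seed=seed, feature_names=fn
            )
            fits, scores = [], []
            for part in parts:
                for alg in sdm.ALGORITHMS:
                    f = fit_model(alg, part, background=bg, seed=seed)
                    fits.append(f)
                    scores.append(score_fit(f, part.X_test, part.y_test))
            ens = build_ensemble(fits, scores, uses_dispersal=use_d)
            smap = project(ens, stack, dispersal_layer=disp if use_d else None)
            surfaces[use_d] = smap.grid.data.ravel()
        cum = disp.grid.data.ravel()
        far = cum >= np.quantile(cum, 0.9)
        diffs.append(surfaces[True][far].mean() - surfaces[False][far].mean())
    assert np.mean(diffs) <= 0


class TestScenarioSpec:
    def test_pairings_enforced(self):
        ScenarioSpec("rcp45", "GOV", "limited", "2050")
        ScenarioSpec("rcp85", "BAU", "none", "2050")
        ScenarioSpec()
        with pytest.raises(ValueError):
            ScenarioSpec("rcp45", "BAU", "none", "2050")
        with pytest.raises(ValueError):
            ScenarioSpec("current", "GOV", "none", "present")
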