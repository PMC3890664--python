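"""Envelope model, Schoener's D, identity test, range maps, AUC, importance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from intdelim.datatypes import OccurrenceSet, SuitabilitySurface, ValidationError
from intdelim.niche import (
    ClimateEnvelope,
    auc,
    background_sample,
    extract_climate,
    identity_test,
    normalize,
    predict_surface,
    range_map,
    ranges_disjoint,
    schoener_D,
    variable_importance,
)
from intdelim.simulate import TaxonSpec, WorldSpec, gen_occurrences, gen_world


class _Scores:
    """Stand-in model whose predictions are the first input column."""

    def predict(self, X):
        return np.asarray(X, dtype=float)[:, 0]


class TestExtractClimate:
    def test_duplicate_cell_collapses_to_one_row(self, small_stack):
        occ = OccurrenceSet("sp", np.array([[0.5, 2.5], [0.6, 2.4]]))
        assert extract_climate(occ, small_stack).shape == (1, 2)

    def test_record_outside_extent_dropped(self, small_stack):
        occ = OccurrenceSet("sp", np.array([[0.5, 2.5], [50.0, 50.0]]))
        assert extract_climate(occ, small_stack).shape == (1, 2)

    def test_all_records_invalid_is_an_error(self, small_stack):
        occ = OccurrenceSet("sp", np.array([[2.5, 0.5]]))  # nodata corner
        with pytest.raises(ValidationError):
            extract_climate(occ, small_stack)


class TestClimateEnvelope:
    def test_training_median_scores_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        model = ClimateEnvelope().fit(X)
        med = np.median(X, axis=0, keepdims=True)
        assert model.predict(med)[0] == pytest.approx(1.0)

    def test_cell_beyond_every_range_scores_zero(self):
        model = ClimateEnvelope().fit(np.arange(10.0).reshape(-1, 2))
        assert model.predict(np.array([[1e6, 1e6]]))[0] == 0.0

    def test_linear_decay_between_percentile_and_max(self):
        # training 0..100, q=(0.05,0.95): 97.5 is halfway from the 95th
        # percentile (95) to the max (100)
        model = ClimateEnvelope().fit(np.arange(101.0).reshape(-1, 1))
        assert model.predict(np.array([[97.5]]))[0] == pytest.approx(0.5)

    def test_constant_layer_scores_one_at_its_value(self):
        X = np.column_stack([np.full(20, 7.0), np.arange(20.0)])
        model = ClimateEnvelope().fit(X)
        assert model.predict(np.array([[7.0, 10.0]]))[0] == pytest.approx(1.0)

    def test_too_few_training_rows_rejected(self):
        with pytest.raises(ValidationError):
            ClimateEnvelope().fit(np.zeros((4, 2)))

    def test_sklearn_param_protocol(self):
        model = ClimateEnvelope(q_lower=0.1, q_upper=0.9)
        assert model.get_params() == {"q_lower": 0.1, "q_upper": 0.9}
        model.set_params(q_lower=0.2)
        assert model.q_lower == 0.2


class TestNormalize:
    def test_sums_to_one(self, small_stack, occ_on_grid):
        model = ClimateEnvelope().fit(extract_climate(occ_on_grid, small_stack))
        surf = normalize(predict_surface(model, small_stack))
        assert surf.values[surf.mask].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, small_stack, occ_on_grid):
        model = ClimateEnvelope().fit(extract_climate(occ_on_grid, small_stack))
        raw = predict_surface(model, small_stack)
        scaled = SuitabilitySurface(raw.values * 7.3, raw.mask)
        np.testing.assert_allclose(normalize(raw).values, normalize(scaled).values)

    def test_masking_renormalizes_over_remainder(self, small_stack, occ_on_grid):
        model = ClimateEnvelope().fit(extract_climate(occ_on_grid, small_stack))
        raw = predict_surface(model, small_stack)
        mask = raw.mask.copy()
        mask[0, :] = False
        reduced = normalize(SuitabilitySurface(np.where(mask, raw.values, 0.0), mask))
        assert reduced.values[mask].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_surface_rejected(self, small_stack):
        surf = SuitabilitySurface(np.zeros((3, 3)), small_stack.mask)
        with pytest.raises(ValidationError):
            normalize(surf)


class TestSchoenerD:
    def _surface(self, weights):
        values = np.asarray(weights, dtype=float)
        return SuitabilitySurface(values / values.sum(), np.ones_like(values, dtype=bool))

    def test_identical_surfaces_give_one(self):
        s = self._surface([[1, 2], [3, 4]])
        assert schoener_D(s, s) == 1.0

    def test_disjoint_supports_give_zero(self):
        a = self._surface([[1, 1], [0, 0]])
        b = self._surface([[0, 0], [1, 1]])
        assert schoener_D(a, b) == 0.0

    def test_two_cell_half_overlap(self):
        a = self._surface([[1.0, 0.0]])
        b = self._surface([[0.5, 0.5]])
        assert schoener_D(a, b) == pytest.approx(0.5)

    def test_unnormalized_input_rejected(self):
        a = self._surface([[1, 1]])
        bad = SuitabilitySurface(np.array([[2.0, 2.0]]), np.ones((1, 2), dtype=bool))
        with pytest.raises(ValidationError):
            schoener_D(a, bad)

    @given(
        wa=st.lists(st.floats(0.01, 10), min_size=4, max_size=4),
        wb=st.lists(st.floats(0.01, 10), min_size=4, max_size=4),
        perm=st.permutations(range(4)),
    )
    def test_symmetric_and_relabeling_invariant(self, wa, wb, perm):
        a = self._surface([wa])
        b = self._surface([wb])
        d1 = schoener_D(a, b)
        assert d1 == pytest.approx(schoener_D(b, a))
        ap = self._surface([[wa[i] for i in perm]])
        bp = self._surface([[wb[i] for i in perm]])
        assert schoener_D(ap, bp) == pytest.approx(d1)
        assert 0.0 <= d1 <= 1.0


class TestIdentityTest:
    @pytest.fixture
    def world(self):
        stack = gen_world(WorldSpec(seed=42))
        spec = TaxonSpec("A", niche={"layer1": (5.0, 2.0)}, n_occurrences=20)
        occ_a = gen_occurrences(spec, stack, seed=1)
        occ_b = gen_occurrences(TaxonSpec("B", niche={"layer1": (5.0, 2.0)}, n_occurrences=20), stack, seed=2)
        return stack, occ_a, occ_b

    def test_null_distribution_shape_and_p_floor(self, world):
        stack, occ_a, occ_b = world
        res = identity_test(occ_a, occ_b, stack, reps=100, seed=0)
        assert len(res.null_Ds) == 100
        assert res.p_value >= 1 / 101
        assert 0.0 <= res.D_obs <= 1.0

    def test_exactly_reproducible_given_seed(self, world):
        stack, occ_a, occ_b = world
        r1 = identity_test(occ_a, occ_b, stack, reps=25, seed=7)
        r2 = identity_test(occ_a, occ_b, stack, reps=25, seed=7)
        assert r1.D_obs == r2.D_obs
        np.testing.assert_array_equal(r1.null_Ds, r2.null_Ds)

    def test_tiny_pooled_sample_rejected(self, small_stack):
        a = OccurrenceSet("a", np.array([[0.5, 2.5], [1.5, 2.5], [2.5, 2.5], [0.5, 1.5], [1.5, 1.5]]))
        b = OccurrenceSet("b", np.array([[2.5, 1.5], [0.5, 0.5]]))
        with pytest.raises(ValidationError, match="pooled"):
            identity_test(a, b, small_stack, reps=5, seed=0)


class TestRangeMap:
    def test_threshold_one_when_all_presences_score_one(self, small_stack, occ_on_grid):
        class Ones:
            def predict(self, X):
                return np.ones(len(X))

        rm = range_map(Ones(), small_stack, occ_on_grid)
        assert rm.threshold == 1.0

    def test_identical_maps_not_disjoint(self, small_stack, occ_on_grid):
        model = ClimateEnvelope().fit(extract_climate(occ_on_grid, small_stack))
        rm = range_map(model, small_stack, occ_on_grid)
        assert not ranges_disjoint(rm, rm)

    def test_separate_halves_are_disjoint(self):
        from intdelim.niche import RangeMap

        a = RangeMap(np.array([[True, False], [True, False]]), 0.5)
        b = RangeMap(np.array([[False, True], [False, True]]), 0.5)
        assert ranges_disjoint(a, b)


class TestAuc:
    def test_perfect_separation(self):
        assert auc(_Scores(), [[10.0], [9.0]], [[1.0], [2.0]]) == 1.0

    def test_enumerated_pairs(self):
        assert auc(_Scores(), [[0.9], [0.7]], [[0.8], [0.1]]) == pytest.approx(0.75)

    def test_null_model_near_half(self):
        rng = np.random.default_rng(1)
        pres = rng.normal(size=(400, 1))
        bg = rng.normal(size=(400, 1))
        assert auc(_Scores(), pres, bg) == pytest.approx(0.5, abs=0.08)


class TestVariableImportance:
    @pytest.fixture
    def driven_world(self):
        stack = gen_world(WorldSpec(seed=9))
        occ = gen_occurrences(
            TaxonSpec("A", niche={"layer1": (5.0, 1.0)}, n_occurrences=30), stack, seed=3
        )
        model = ClimateEnvelope().fit(extract_climate(occ, stack))
        return stack, occ, model

    def test_sums_to_100(self, driven_world):
        stack, occ, model = driven_world
        vi = variable_importance(model, stack, occ, seed=0)
        assert sum(vi.values()) == pytest.approx(100.0, abs=1e-6)

    def test_driving_layer_ranks_first(self, driven_world):
        stack, occ, model = driven_world
        ranked_first = 0
        for seed in range(20):
            occ_s = gen_occurrences(
                TaxonSpec("A", niche={"layer1": (5.0, 1.0)}, n_occurrences=30),
                stack, seed=100 + seed,
            )
            m = ClimateEnvelope().fit(extract_climate(occ_s, stack))
            vi = variable_importance(m, stack, occ_s, seed=seed)
            ranked_first += max(vi, key=vi.get) == "layer1"
        assert ranked_first >= 19

    def test_single_layer_gets_everything(self):
        stack = gen_world(WorldSpec(seed=5, n_layers=1))
        occ = gen_occurrences(
            TaxonSpec("A", niche={"layer1": (5.0, 1.0)}, n_occurrences=25), stack, seed=1
        )
        model = ClimateEnvelope().fit(extract_climate(occ, stack))
        vi = variable_importance(model, stack, occ, seed=0)
        assert vi == {"layer1": pytest.approx(100.0)}

    def test_background_sample_reproducible(self, small_stack):
        b1 = background_sample(small_stack, n=4, seed=3)
        b2 = background_sample(small_stack, n=4, seed=3)
        np.testing.assert_array_equal(b1, b2)
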