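import math

import numpy as np
import pytest

from randomknn import (
    RknnParams,
    SyntheticSpec,
    generate,
    geometric_stage,
    linear_stage,
    rknn_fs,
)
from randomknn.selection import (
    best_index,
    geometric_retention,
    n_geometric_iterations,
    n_linear_steps,
    pre_max_index,
)


def closed_form_sizes(p, q, min_dim=4):
    """Independent arithmetic oracle for the stage-1 size schedule."""
    ni = math.floor(math.log(min_dim / p) / math.log(1 - q)) if p > min_dim else 0
    sizes = [p]
    for _ in range(2, ni + 1):
        nxt = math.ceil(sizes[-1] * (1 - q))
        if nxt < min_dim:
            break
        sizes.append(nxt)
    return sizes


class TestScheduleArithmetic:
    @pytest.mark.parametrize(
        "p,q,want_ni",
        [
            (100, 0.5, 4),
            (5327, 0.2, 32),   # floor(ln(4/5327)/ln(0.8))
            (2000, 0.2, 27),   # floor(ln(4/2000)/ln(0.8))
            (500, 0.2, 21),
            (4, 0.5, 0),
        ],
    )
    def test_geometric_iteration_count(self, p, q, want_ni):
        assert n_geometric_iterations(p, q) == want_ni
        # cross-check against direct arithmetic, not a copy of the formula
        if p > 4:
            assert want_ni == int(math.log(4 / p) / math.log(1 - q))

    def test_retention_rule_100_half(self):
        sizes = [100]
        for _ in range(3):
            sizes.append(geometric_retention(sizes[-1], 0.5))
        assert sizes == [100, 50, 25, 13]

    @pytest.mark.parametrize(
        "p_start,d,want", [(10, 1, 6), (10, 3, 2), (10, 6, 1), (10, 7, 0), (4, 1, 0)]
    )
    def test_linear_step_count(self, p_start, d, want):
        assert n_linear_steps(p_start, d) == want

    @pytest.mark.parametrize("p,q", [(37, 0.37), (100, 0.9), (11, 0.55), (64, 0.5)])
    def test_guard_never_undershoots_min_dim(self, p, q):
        assert min(closed_form_sizes(p, q)) >= 4


class TestChosenIterationRules:
    def test_pre_max_is_iteration_before_peak(self):
        # accs (0.70, 0.80, 0.90, 0.85): peak at 3rd -> pre-max is 2nd
        assert pre_max_index([0.70, 0.80, 0.90, 0.85]) == 1

    def test_pre_max_clamped_when_peak_is_first(self):
        assert pre_max_index([0.9, 0.8, 0.7]) == 0

    def test_argmax_ties_take_earliest_larger_set(self):
        assert best_index([0.8, 0.9, 0.9]) == 1
        assert pre_max_index([0.8, 0.9, 0.9]) == 0


@pytest.fixture(scope="module")
def sel_data():
    spec = SyntheticSpec(n=40, p=100, c=2, n_informative=6, shift=1.5, seed=3)
    return generate(spec)


SEL_PARAMS = RknnParams(k=3, r=60, q=0.5, seed=17)


class TestGeometricStage:
    def test_sizes_follow_closed_form(self, sel_data):
        data, _ = sel_data
        trace = geometric_stage(data, SEL_PARAMS)
        assert trace.sizes == closed_form_sizes(100, 0.5)  # [100, 50, 25, 13]
        assert trace.chosen_index == pre_max_index(trace.accuracies)

    def test_monotone_containment(self, sel_data):
        data, _ = sel_data
        trace = geometric_stage(data, SEL_PARAMS)
        for prev, cur in zip(trace.iterations, trace.iterations[1:]):
            assert set(cur.feature_ids) < set(prev.feature_ids)

    def test_p_at_min_dim_single_evaluation(self, sel_data):
        data, _ = sel_data
        small = data.subset_features(range(4))
        with pytest.warns(UserWarning, match="nothing to eliminate"):
            trace = geometric_stage(small, RknnParams(k=3, r=20, seed=1))
        assert trace.sizes == [4]
        assert trace.chosen_index == 0


class TestLinearStage:
    def test_step_counts_and_sizes(self, sel_data):
        data, _ = sel_data
        start = list(data.feature_ids[:10])
        trace = linear_stage(data, start, RknnParams(k=3, r=30, d=1, seed=5))
        assert trace.sizes == [10, 9, 8, 7, 6, 5, 4]
        assert trace.chosen_index == best_index(trace.accuracies)

    def test_large_d_single_step(self, sel_data):
        data, _ = sel_data
        start = list(data.feature_ids[:10])
        trace = linear_stage(data, start, RknnParams(k=3, r=30, d=6, seed=5))
        assert trace.sizes == [10, 4]

    def test_start_at_min_dim_returned_unchanged(self, sel_data):
        data, _ = sel_data
        start = list(data.feature_ids[:4])
        with pytest.warns(UserWarning, match="unchanged"):
            trace = linear_stage(data, start, RknnParams(k=3, r=20, seed=5))
        assert trace.sizes == [4]
        assert trace.chosen.feature_ids == tuple(start)


class TestRknnFs:
    def test_determinism_same_seed_identical(self, sel_data):
        data, _ = sel_data
        a = rknn_fs(data, SEL_PARAMS)
        b = rknn_fs(data, SEL_PARAMS)
        assert a.selected == b.selected
        assert a.geometric_trace.accuracies == b.geometric_trace.accuracies
        assert a.linear_trace.accuracies == b.linear_trace.accuracies

    def test_selected_at_least_min_dim_and_contained(self, sel_data):
        data, _ = sel_data
        res = rknn_fs(data, SEL_PARAMS)
        assert len(res.selected) >= SEL_PARAMS.min_dim
        assert set(res.selected) <= set(data.feature_ids)
        # linear stage starts from the geometric pre-max set
        assert set(res.linear_trace.iterations[0].feature_ids) == set(
            res.geometric_trace.chosen.feature_ids
        )

    def test_stage1_only_returns_best_geometric_set(self, sel_data):
        data, _ = sel_data
        res = rknn_fs(data, SEL_PARAMS, stage1_only=True)
        assert res.linear_trace is None
        geo = res.geometric_trace
        assert res.selected == geo.iterations[best_index(geo.accuracies)].feature_ids

    def test_p_equal_min_dim_identity(self):
        spec = SyntheticSpec(n=20, p=4, c=2, n_informative=2, shift=2.0, seed=9)
        data, _ = generate(spec)
        with pytest.warns(UserWarning):
            res = rknn_fs(data, RknnParams(k=3, r=20, seed=2))
        assert set(res.selected) == set(data.feature_ids)

    def test_planted_recovery_small(self, sel_data):
        data, planted = sel_data
        res = rknn_fs(data, RknnParams(k=3, r=300, seed=1))
        assert len(set(res.selected) & set(planted)) >= 4
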