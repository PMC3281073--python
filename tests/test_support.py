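import numpy as np
import pytest

from randomknn import (
    FeatureSubset,
    ParameterError,
    RknnParams,
    StateError,
    compute_supports,
    partition_samples,
    rank_features,
)
from randomknn.support import SupportRanking

from ._oracles import brute_base_classifier_acc, brute_supports

# the three hand-checked base classifiers used against the tiny fixture:
# subspaces (f1,f2), (f3,f4), (f5,f6) with k=1 and fixed half-splits
TINY_SUBSETS = [(0, 1), (2, 3), (4, 5)]
TINY_PARTITIONS = [
    ([0, 1, 4, 5], [2, 3, 6, 7]),
    ([0, 2, 4, 6], [1, 3, 5, 7]),
    ([1, 3, 5, 7], [0, 2, 4, 6]),
]
# frozen values from the pure-python double-loop oracle (see test below,
# which recomputes them independently)
TINY_ACCS = [1.0, 0.5, 0.25]
TINY_SUPPORTS = {"f1": 1.0, "f2": 1.0, "f3": 0.5, "f4": 0.5, "f5": 0.25, "f6": 0.25}


class TestPartitionSamples:
    @pytest.mark.parametrize("n,sizes", [(4, (2, 2)), (5, (3, 2)), (9, (5, 4))])
    def test_half_split_sizes_base_gets_extra(self, n, sizes):
        base, query = partition_samples(n, "dynamic", np.random.default_rng(0))
        assert (len(base), len(query)) == sizes
        assert sorted(set(base) | set(query)) == list(range(n))
        assert set(base).isdisjoint(query)

    def test_base_smaller_than_k_rejected(self):
        with pytest.raises(ParameterError, match="smaller k"):
            partition_samples(4, "dynamic", np.random.default_rng(0), k=3)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            partition_samples(4, "static", np.random.default_rng(0))

    def test_dynamic_draws_are_balanced(self):
        # each of n=10 samples lands in the base half with prob 1/2; over
        # 200 draws the count must stay within the 3-sigma binomial band
        rng = np.random.default_rng(1)
        counts = np.zeros(10)
        for _ in range(200):
            base, _ = partition_samples(10, "dynamic", rng)
            counts[base] += 1
        assert np.all((counts >= 60) & (counts <= 140))


class TestComputeSupports:
    def test_hand_computed_three_classifier_fixture(self, tiny):
        params = RknnParams(k=1, r=3, seed=0)
        ranking, records = compute_supports(
            tiny,
            params,
            subsets=[FeatureSubset(s) for s in TINY_SUBSETS],
            partitions=TINY_PARTITIONS,
            return_records=True,
        )
        assert [rec.acc for rec in records] == TINY_ACCS
        for fid, want in TINY_SUPPORTS.items():
            j = tiny.feature_ids.index(fid)
            assert ranking.support[j] == want
        assert ranking.mean_acc == pytest.approx(sum(TINY_ACCS) / 3)

    def test_fixture_values_match_independent_double_loop(self, tiny):
        """Recompute the frozen accuracies with the pure-python oracle."""
        X = [list(row) for row in tiny.X]
        for (cols, (b, q), want) in zip(TINY_SUBSETS, TINY_PARTITIONS, TINY_ACCS):
            got = brute_base_classifier_acc(
                X, list(tiny.y), list(tiny.sample_ids), b, q, 1, cols
            )
            assert got == want

    def test_single_classifier_support_equals_its_accuracy(self, tiny):
        params = RknnParams(k=1, r=1, seed=0)
        ranking, records = compute_supports(
            tiny,
            params,
            subsets=[FeatureSubset((0, 1))],
            partitions=[TINY_PARTITIONS[0]],
            return_records=True,
        )
        assert ranking.support[0] == records[0].acc == 1.0
        assert ranking.multiplicity[0] == 1

    def test_support_is_mean_over_containing_classifiers(self, small_synth):
        data, _ = small_synth
        ranking, records = compute_supports(
            data, RknnParams(k=3, r=40, m=6, seed=5), return_records=True
        )
        want, mult = brute_supports(
            [r.subset.indices for r in records], [r.acc for r in records], data.n_features
        )
        for j in range(data.n_features):
            assert ranking.multiplicity[j] == mult[j]
            if mult[j]:
                assert ranking.support[j] == pytest.approx(want[j], rel=1e-12)
            else:
                assert np.isnan(ranking.support[j])

    @pytest.mark.parametrize("mode", ["dynamic", "fixed"])
    def test_conservation_identity(self, small_synth, mode):
        data, _ = small_synth
        params = RknnParams(k=3, r=80, m=5, partition_mode=mode, seed=2)
        rk = compute_supports(data, params)
        lhs = np.nansum(rk.support * rk.multiplicity)
        rhs = rk.m * rk.mean_acc * rk.r
        assert lhs == pytest.approx(rhs, rel=1e-9)
        assert rk.multiplicity.sum() == rk.r * rk.m
        assert np.all((rk.support[rk.defined] >= 0) & (rk.support[rk.defined] <= 1))

    def test_never_sampled_feature_reported_undefined(self, tiny):
        params = RknnParams(k=1, r=2, seed=0)
        with pytest.warns(UserWarning, match="never sampled"):
            ranking = compute_supports(
                tiny,
                params,
                subsets=[FeatureSubset((0, 1)), FeatureSubset((0, 2))],
                partitions=TINY_PARTITIONS[:2],
            )
        assert ranking.multiplicity[5] == 0
        assert np.isnan(ranking.support[5])
        frame = ranking.as_frame()
        unranked = frame[frame.feature_id == "f6"]
        assert unranked["rank"].isna().all()

    def test_fixed_partition_and_seed_bit_identical(self, small_synth):
        data, _ = small_synth
        params = RknnParams(k=3, r=30, partition_mode="fixed", seed=77)
        a = compute_supports(data, params)
        b = compute_supports(data, params)
        assert np.array_equal(a.support, b.support, equal_nan=True)
        assert np.array_equal(a.multiplicity, b.multiplicity)
        assert a.mean_acc == b.mean_acc


def _ranking(ids, supports, mults):
    return SupportRanking(
        feature_ids=tuple(ids),
        support=np.asarray(supports, dtype=float),
        multiplicity=np.asarray(mults, dtype=np.int64),
        mean_acc=0.5,
        r=int(np.sum(mults)),
        m=1,
    )


class TestRankFeatures:
    def test_documented_tie_break(self):
        # equal supports: higher multiplicity first; then id order
        r = _ranking(["a", "b", "c"], [0.9, 0.7, 0.9], [10, 8, 12])
        assert rank_features(r) == ["c", "a", "b"]

    def test_singleton(self):
        r = _ranking(["only", "none"], [0.4, np.nan], [3, 0])
        assert rank_features(r) == ["only", "none"]

    def test_all_undefined_is_state_error(self):
        r = _ranking(["a", "b"], [np.nan, np.nan], [0, 0])
        with pytest.raises(StateError):
            rank_features(r)

    def test_matches_stable_sort_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            ids = [f"f{i}" for i in range(n)]
            sup = rng.choice([0.2, 0.5, 0.8], size=n)  # coarse grid forces ties
            mult = rng.integers(1, 4, size=n)
            got = rank_features(_ranking(ids, sup, mult))
            want = [
                fid
                for fid, _, _ in sorted(
                    zip(ids, sup, mult), key=lambda t: (-t[1], -t[2], t[0])
                )
            ]
            assert got == want
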