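"""The z-score distance engine against brute-force oracles and its
invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olmens.errors import IncomparableTracesError, PairingError
from olmens.features import MeasureVector
from olmens.ranking import (DistanceRecord, aggregate_distance,
                            dataset_stats, distance, rank_models)


def vec(values, protocol="depol", trace_id=""):
    return MeasureVector(values=dict(values), protocol=protocol,
                         trace_id=trace_id)


def brute_force_distance(x, y, sigma):
    """Independent evaluation of the distance formula with plain loops."""
    sq, n = 0.0, 0
    for k in x:
        if k in y and k in sigma \
                and math.isfinite(x[k]) and math.isfinite(y[k]):
            sq += ((x[k] - y[k]) / sigma[k]) ** 2
            n += 1
    return math.sqrt(sq / n)


def random_toy_db(rng, n_models, n_traces, n_measures=4, nan_frac=0.1):
    names = [f"m{i}" for i in range(n_measures)]
    def draw():
        vals = {}
        for k in names:
            vals[k] = float("nan") if rng.random() < nan_frac \
                else float(rng.normal(0, 5))
        return vals
    exp = [vec(draw(), trace_id=f"y{j}") for j in range(n_traces)]
    models = [{"depol": vec(draw(), trace_id=f"x{i}")}
              for i in range(n_models)]
    return models, exp


class TestDatasetStats:
    def test_two_trace_example(self):
        stats = dataset_stats([vec({"a": 1.0}), vec({"a": 3.0})])
        assert stats.mean["a"] == 2.0
        assert stats.sigma["a"] == pytest.approx(math.sqrt(2.0))

    def test_constant_measure_floored_and_flagged(self):
        stats = dataset_stats([vec({"a": 5.0}), vec({"a": 5.0})])
        assert "a" in stats.floored
        assert stats.sigma["a"] > 0

    def test_single_trace_dataset_rejected(self):
        with pytest.raises(ValueError):
            dataset_stats([vec({"a": 1.0})])


class TestDistance:
    def test_identity_is_zero(self):
        x = vec({"a": 1.0, "b": -2.0})
        stats = dataset_stats([x, vec({"a": 2.0, "b": 0.0})])
        assert distance(x, x, stats) == 0.0

    def test_single_measure_one_sigma_apart_is_one(self):
        stats = dataset_stats([vec({"a": 0.0}), vec({"a": 2.0})])
        sig = stats.sigma["a"]
        assert distance(vec({"a": 0.0}), vec({"a": sig}), stats) == \
            pytest.approx(1.0)

    def test_three_measure_brute_force_oracle(self):
        x = vec({"a": 10.5, "b": -74.2, "c": 14.2})
        y = vec({"a": 8.0, "b": -73.8, "c": 11.1})
        stats = dataset_stats([vec({"a": 9.0, "b": -75.0, "c": 12.0}),
                               vec({"a": 7.0, "b": -72.0, "c": 16.0}),
                               vec({"a": 11.0, "b": -74.0, "c": 13.0})])
        expected = brute_force_distance(x.values, y.values, stats.sigma)
        assert distance(x, y, stats) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        x = vec({"a": 1.0, "b": 2.0})
        y = vec({"a": -1.0, "b": 5.0})
        stats = dataset_stats([x, y])
        assert distance(x, y, stats) == distance(y, x, stats)

    def test_unit_invariance(self):
        """Rescaling a measure's unit in x, y, and sigma simultaneously
        leaves the distance unchanged."""
        x = vec({"a": 3.0, "b": 1.0})
        y = vec({"a": 5.0, "b": 2.0})
        stats = dataset_stats([vec({"a": 2.0, "b": 0.5}),
                               vec({"a": 6.0, "b": 2.5})])
        d0 = distance(x, y, stats)
        k = 1000.0
        xs = vec({"a": k * 3.0, "b": 1.0})
        ys = vec({"a": k * 5.0, "b": 2.0})
        stats2 = dataset_stats([vec({"a": k * 2.0, "b": 0.5}),
                                vec({"a": k * 6.0, "b": 2.5})])
        assert distance(xs, ys, stats2) == pytest.approx(d0, rel=1e-12)

    def test_monotone_in_single_measure_error(self):
        y = vec({"a": 0.0, "b": 0.0})
        stats = dataset_stats([vec({"a": -1.0, "b": -1.0}),
                               vec({"a": 1.0, "b": 1.0})])
        ds = [distance(vec({"a": e, "b": 0.5}), y, stats)
              for e in (0.0, 0.5, 1.0, 2.0)]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_invalid_measures_dropped_pairwise(self):
        x = vec({"a": 1.0, "b": float("nan")})
        y = vec({"a": 2.0, "b": 0.0})
        stats = dataset_stats([vec({"a": 0.0, "b": -1.0}),
                               vec({"a": 4.0, "b": 1.0})])
        lone = distance(x, y, stats)
        assert lone == pytest.approx(
            abs(1.0 - 2.0) / stats.sigma["a"])

    def test_no_shared_valid_measures_raises(self):
        x = vec({"a": float("nan")})
        y = vec({"a": 1.0})
        stats = dataset_stats([vec({"a": 0.0}), vec({"a": 2.0})])
        with pytest.raises(IncomparableTracesError):
            distance(x, y, stats)

    def test_protocol_mismatch_raises(self):
        stats = dataset_stats([vec({"a": 0.0}), vec({"a": 2.0})])
        with pytest.raises(PairingError):
            distance(vec({"a": 1.0}, protocol="hyper"),
                     vec({"a": 1.0}, protocol="depol"), stats)


class TestAggregate:
    def test_single_trace_equals_pair_distance(self):
        x = {"depol": vec({"a": 1.0})}
        exp = [vec({"a": 3.0}, trace_id="y0"), vec({"a": 5.0},
                                                   trace_id="y1")]
        stats = dataset_stats(exp)
        rec = aggregate_distance(x, exp[:1], stats)
        assert rec.d_x == distance(x["depol"], exp[0], stats)

    def test_mean_of_two(self):
        stats = dataset_stats([vec({"a": 0.0}), vec({"a": 1.0})])
        sig = stats.sigma["a"]
        x = {"depol": vec({"a": 0.0})}
        exp = [vec({"a": 2.0 * sig}, trace_id="y0"),
               vec({"a": 4.0 * sig}, trace_id="y1")]
        rec = aggregate_distance(x, exp, stats)
        assert rec.d_x == pytest.approx(3.0)

    def test_toy_database_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        models, exp = random_toy_db(rng, n_models=5, n_traces=6)
        stats = dataset_stats(exp)
        for i, mv in enumerate(models):
            rec = aggregate_distance(mv, exp, stats, model_id=i)
            direct = np.mean([brute_force_distance(
                mv["depol"].values, y.values, stats.sigma) for y in exp])
            assert rec.d_x == pytest.approx(direct, abs=1e-12)


class TestRanking:
    def test_basic_ordering(self):
        recs = [DistanceRecord(0, 3.0), DistanceRecord(1, 1.0),
                DistanceRecord(2, 2.0)]
        df = rank_models(recs)
        assert list(df["model_id"]) == [1, 2, 0]
        assert list(df["rank"]) == [1, 2, 3]

    def test_ties_break_by_model_id(self):
        recs = [DistanceRecord(i, 1.0) for i in (5, 3, 9)]
        df = rank_models(recs)
        assert list(df["model_id"]) == [3, 5, 9]

    def test_nan_distance_excluded(self):
        recs = [DistanceRecord(0, 1.0), DistanceRecord(1, float("nan"))]
        df = rank_models(recs)
        assert list(df["model_id"]) == [0]
        assert df.attrs["excluded"] == [1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        base = [DistanceRecord(i, float(d)) for i, d in
                enumerate([3.0, 1.5, 2.2, 0.7, 5.1, 2.2, 4.0, 1.5])]
        shuffled = [base[i] for i in order]
        df = rank_models(shuffled)
        assert list(df["model_id"]) == [3, 1, 7, 2, 5, 0, 6, 4]

    def test_oracle_equivalence_on_toy_databases(self):
        """Full pipeline (stats -> distances -> rank) equals a plain-loop
        oracle on random toy databases of <= 10 models."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_models = int(rng.integers(2, 11))
            models, exp = random_toy_db(rng, n_models, n_traces=4)
            stats = dataset_stats(exp)
            recs = [aggregate_distance(m, exp, stats, model_id=i)
                    for i, m in enumerate(models)]
            df = rank_models(recs)
            oracle = sorted(
                range(n_models),
                key=lambda i: (np.mean([brute_force_distance(
                    models[i]["depol"].values, y.values, stats.sigma)
                    for y in exp]), i))
            assert list(df["model_id"]) == oracle
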