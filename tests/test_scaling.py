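"""Static thresholds, exact 1-D k-means and dynamic-scale behaviour."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from oquare import (
    DynamicScale,
    MetricVector,
    ScoreVector,
    StaticScale,
    dynamic_score,
    fit_dynamic_scale,
    kmeans_1d,
    score_vector,
    static_score,
)
from oquare.metrics import METRIC_IDS
from oquare.scaling import HIGHER_BETTER, LOWER_BETTER

DITONTO_SEQUENCE = (11, 11, 11, 11, 13, 13, 14, 13, 13, 13, 13, 12, 12, 12)


class TestStaticScale:
    @pytest.mark.parametrize(
        "metric,raw,expected",
        [
            ("TMOnto", 1.28, 5),     # worked scaling example
            ("RROnto", 0.74, 4),     # percent metric, 74 %
            ("DITOnto", 11, 1),      # depth beyond the worst bin
            ("LCOMOnto", 2.0, 5),    # boundary belongs to the better bin
            ("LCOMOnto", 2.0001, 4),
            ("NOCOnto", 3, 5),
            ("NOCOnto", 13, 1),
            ("WMCOnto", 15, 2),
            ("ANOnto", 0.2, 1),      # 20 % is still the worst percent bin
            ("ANOnto", 0.81, 5),
            ("CROnto", 1.5, 5),      # ratios over 100 % clamp to 5
            ("TMOnto", 0.1, 5),      # fractions below the lowest bin clamp up
        ],
    )
    def test_threshold_table(self, metric, raw, expected):
        assert static_score(metric, raw) == expected

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            static_score("FOOnto", 1.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            static_score("TMOnto", float("nan"))

    @given(
        metric=st.sampled_from(sorted(LOWER_BETTER | HIGHER_BETTER)),
        a=st.floats(0, 50, allow_nan=False),
        b=st.floats(0, 50, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_direction_monotonicity(self, metric, a, b):
        lo, hi = sorted((a, b))
        s_lo, s_hi = static_score(metric, lo), static_score(metric, hi)
        if metric in LOWER_BETTER:
            assert s_lo >= s_hi
        else:
            assert s_lo <= s_hi


def brute_force_partition(values, k):
    """Oracle: minimise within-cluster SSE over all contiguous partitions."""
    xs = sorted(values)
    n = len(xs)

    def sse(chunk):
        m = sum(chunk) / len(chunk)
        return sum((x - m) ** 2 for x in chunk)

    best, best_cost = None, float("inf")
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        clusters = [xs[bounds[i]: bounds[i + 1]] for i in range(k)]
        cost = sum(sse(c) for c in clusters)
        if cost < best_cost - 1e-12:
            best, best_cost = clusters, cost
    return best, best_cost


class TestKMeans:
    def test_two_well_separated_groups(self):
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 10.0, 10.2, 9.9, 10.1, 10.05]
        clusters = kmeans_1d(values, 2)
        oracle, _ = brute_force_partition(values, 2)
        assert clusters == oracle

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_exhaustive_minimisation(self, seed, k):
        import random

        rng = random.Random(seed)
        values = [round(rng.uniform(0, 10), 2) for _ in range(12)]
        k_eff = min(k, len(set(values)))
        clusters = kmeans_1d(values, k)

        def sse(chunk):
            m = sum(chunk) / len(chunk)
            return sum((x - m) ** 2 for x in chunk)

        _, oracle_cost = brute_force_partition(values, k_eff)
        assert sum(sse(c) for c in clusters) == pytest.approx(oracle_cost)

    def test_k_capped_at_distinct_values(self):
        assert kmeans_1d([3.0, 3.0, 3.0], 5) == [[3.0, 3.0, 3.0]]


class TestDynamicScale:
    def test_ditonto_corpus_interval_structure(self):
        scale = fit_dynamic_scale({"DITOnto": list(DITONTO_SEQUENCE)})
        assert scale.intervals["DITOnto"] == {
            5: (11, 11), 4: (12, 12), 3: (13, 13), 2: (14, 14)
        }  # score 1 stays empty: only 4 distinct values observed

    def test_ditonto_trajectory(self):
        scale = fit_dynamic_scale({"DITOnto": list(DITONTO_SEQUENCE)})
        scores = [dynamic_score(scale, "DITOnto", v) for v in DITONTO_SEQUENCE]
        assert scores[0] == 5          # starts at the best observed depth
        assert scores[6] == 2          # dips when the depth peaks at 14
        assert scores[-1] == 4         # ends one level below the best

    def test_constant_sequence_scores_five(self):
        scale = fit_dynamic_scale({"ANOnto": [0.5] * 6})
        assert scale.intervals["ANOnto"] == {5: (0.5, 0.5)}
        assert dynamic_score(scale, "ANOnto", 0.5) == 5
        assert dynamic_score(scale, "ANOnto", 99.0) == 5  # clamp to the hull

    def test_best_observed_value_always_scores_five(self):
        values = [2.0, 3.5, 8.0, 1.5, 6.0]
        lo_scale = fit_dynamic_scale({"LCOMOnto": values})
        hi_scale = fit_dynamic_scale({"RROnto": values})
        assert dynamic_score(lo_scale, "LCOMOnto", min(values)) == 5
        assert dynamic_score(hi_scale, "RROnto", max(values)) == 5

    @given(
        data=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=12),
        metric=st.sampled_from(sorted(LOWER_BETTER | HIGHER_BETTER)),
    )
    @settings(derandomize=True, max_examples=150)
    def test_direction_monotonicity(self, data, metric):
        scale = fit_dynamic_scale({metric: data})
        a, b = min(data), max(data)
        s_a = dynamic_score(scale, metric, a)
        s_b = dynamic_score(scale, metric, b)
        if metric in LOWER_BETTER:
            assert s_a >= s_b
        else:
            assert s_a <= s_b
        assert all(
            1 <= dynamic_score(scale, metric, v) <= 5 for v in data
        )

    def test_json_round_trip(self):
        scale = fit_dynamic_scale({"DITOnto": list(DITONTO_SEQUENCE)})
        again = DynamicScale.from_json(scale.to_json())
        assert again.intervals == scale.intervals


class TestScoreVector:
    def test_componentwise_application(self):
        m = MetricVector({"TMOnto": 1.28, "RROnto": 0.74, "DITOnto": 11.0})
        sv = score_vector(m, StaticScale(), version="v1")
        assert sv.scores["TMOnto"] == 5
        assert sv.scores["RROnto"] == 4
        assert sv.scores["DITOnto"] == 1
        assert sv.scores["ANOnto"] is None  # undefined raw -> undefined score
        assert sv.r == len(METRIC_IDS)
        assert sv.scale == "static"
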