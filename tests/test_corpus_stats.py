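"""Wilcoxon ranking of version pairs and the activity/quality PCA."""

import numpy as np
import pytest
from scipy import stats as sps

from oquare import ActivityDelta, ChangeStatistics, MetricVector, VersionedCorpus, VersionRecord
from oquare.corpus_stats import (
    exact_signed_rank_p,
    pca_activity,
    pearson_pairs,
    wilcoxon_consecutive,
)
from oquare.metrics import METRIC_IDS


def record(version, values):
    return VersionRecord(
        version=version, metrics=MetricVector(dict(zip(METRIC_IDS, values)))
    )


class TestExactSignedRank:
    def test_fourteen_equal_positive_differences(self):
        # all-positive tied sample: the rank sum is maximal, so the
        # one-sided tail is exactly 2^-14
        assert exact_signed_rank_p([0.1] * 14) == pytest.approx(0.5**14)

    def test_all_zero_sample_has_no_test(self):
        assert exact_signed_rank_p([0.0] * 5) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.2, 1.0, 14), 6)
        assert len(set(np.abs(d))) == len(d)  # tie-free
        mine = exact_signed_rank_p(d)
        ref = sps.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_null_enumeration_oracle_small_n(self):
        # brute force over all sign assignments for n = 6
        d = [0.3, -0.5, 1.2, 0.9, -0.1, 0.7]
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[np.asarray(d) > 0].sum()
        count = 0
        total = 0
        for mask in range(2**6):
            w = sum(ranks[i] for i in range(6) if mask >> i & 1)
            total += 1
            if w >= w_obs:
                count += 1
        assert exact_signed_rank_p(d) == pytest.approx(count / total)


class TestWilcoxonConsecutive:
    def test_identical_versions_are_degenerate(self):
        base = [1.0 + i for i in range(14)]
        corpus = VersionedCorpus([record("v1", base), record("v2", base)])
        (result,) = wilcoxon_consecutive(corpus)
        assert result.degenerate
        assert result.p_value is None
        assert result.estimate == 0

    def test_uniformly_larger_changes_rank_later(self):
        base = np.linspace(1, 14, 14)
        small = base + 0.01
        big = small + 1.0
        corpus = VersionedCorpus(
            [record("v1", base), record("v2", small), record("v3", big)]
        )
        results = wilcoxon_consecutive(corpus)
        assert [r.version for r in results] == ["v2", "v3"]
        assert results[0].estimate < results[1].estimate

    def test_estimate_is_median_absolute_difference(self):
        base = np.zeros(14)
        nxt = np.arange(14, dtype=float)  # |diffs| = 0..13, median 6.5
        corpus = VersionedCorpus([record("v1", base), record("v2", nxt)])
        (result,) = wilcoxon_consecutive(corpus)
        assert result.estimate == pytest.approx(6.5)

    def test_requires_two_versions(self):
        with pytest.raises(ValueError):
            wilcoxon_consecutive(VersionedCorpus([record("v1", np.ones(14))]))


def stats_row(back, fwd, mean):
    return ChangeStatistics(
        forward_mean=None, backward_mean=None, mean_change=mean,
        magnitude=0.0, forward_size=fwd, backward_size=back,
    )


class TestPCA:
    def test_rank_one_structure(self):
        # two perfectly correlated variables load equally on factor 1
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        stats = [stats_row(v, v, 0.123 * i) for i, v in enumerate(x)]
        activity = [ActivityDelta(0, 0, 0)] * 20
        with pytest.warns(UserWarning, match="constant"):
            result = pca_activity(stats, activity)
        names = list(result.variables)
        i = names.index("Dynamic.Backward.Size")
        j = names.index("Dynamic.Forward.Size")
        assert abs(result.loadings[i, 0]) == pytest.approx(abs(result.loadings[j, 0]))

    def test_two_factor_recovery(self):
        # simulate two independent latent factors driving three variables each
        rng = np.random.default_rng(42)
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        noise = lambda: rng.normal(scale=0.05, size=n)
        stats = [
            stats_row(b, f, m)
            for b, f, m in zip(f2 + noise(), f2 + noise(), f2 + noise())
        ]
        activity = [
            ActivityDelta(abs(int(10 * a)), abs(int(10 * b)), abs(int(10 * c)))
            for a, b, c in zip(f1 + noise(), f1 + noise(), f1 + noise())
        ]
        result = pca_activity(stats, activity)
        # the two equal-size blocks give near-equal eigenvalues, so the
        # factor pair is identified only up to rotation: compare loading
        # *directions* instead — same-block vectors nearly parallel,
        # cross-block nearly orthogonal
        L = result.loadings
        unit = L / np.linalg.norm(L, axis=1, keepdims=True)
        activity_vars = [0, 1, 2]  # new, changed, deleted
        change_vars = [3, 4, 5]
        for block in (activity_vars, change_vars):
            for i in block:
                for j in block:
                    assert abs(unit[i] @ unit[j]) > 0.95
        for i in activity_vars:
            for j in change_vars:
                assert abs(unit[i] @ unit[j]) < 0.3
        assert sum(result.explained_variance) > 0.9

    def test_independent_variables_share_variance(self):
        rng = np.random.default_rng(7)
        n = 4000
        X = rng.normal(size=(n, 6))
        stats = [stats_row(*row[:3]) for row in X]
        activity = [ActivityDelta(0, 0, 0)] * n
        # feed the raw matrix directly: activity columns replaced by noise
        from oquare.corpus_stats import _pca_correlation, PCA_VARIABLES

        result = _pca_correlation(X, PCA_VARIABLES)
        assert result.explained_variance[0] == pytest.approx(1 / 6, abs=0.03)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            pca_activity([stats_row(0, 0, 0)] * 2, [ActivityDelta(0, 0, 0)] * 2)


class TestPearson:
    def test_identical_columns(self):
        x = [1.0, 2.0, 3.0, 4.0]
        (res,) = pearson_pairs({"a": x, "b": x})
        assert res[2] == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        x = [1.0, 2.0, 3.0, 4.0]
        (res,) = pearson_pairs({"a": x, "b": [-v for v in x]})
        assert res[2] == pytest.approx(-1.0)

    def test_sampled_bivariate_normal(self):
        rng = np.random.default_rng(3)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=1000).T
        (res,) = pearson_pairs({"x": x, "y": y})
        assert res[2] == pytest.approx(rho, abs=0.05)

    def test_all_fifteen_pairs(self):
        rng = np.random.default_rng(1)
        cols = {f"v{i}": rng.normal(size=10) for i in range(6)}
        assert len(pearson_pairs(cols)) == 15

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_pairs({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
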