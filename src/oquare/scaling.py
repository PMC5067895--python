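"""Discretisation of raw metric values into quality scores 1-5.

Two scaling functions are provided:

* the **static scale**: a fixed threshold table per metric, derived from
  object-oriented engineering best practice (1 = not acceptable, 3 =
  minimally acceptable, 5 = exceeds requirements).  Ratio-valued metrics
  (RROnto, AROnto, INROnto, CROnto, ANOnto) are expressed as percentages
  before binning; values outside the printed bins clamp to the nearest
  score.
* the **dynamic scale**: a corpus-fitted discretisation obtained by
  clustering the raw values observed across all versions of one ontology
  into k = 5 groups (fewer when fewer distinct values exist), oriented so
  that the best observed value always scores 5.  When fewer than 5 clusters
  exist the *low* scores are left empty.

The clustering is an exact 1-D k-means: a dynamic programme over contiguous
partitions of the sorted values that globally minimises the within-cluster
sum of squares.  It is seed-free and deterministic, and coincides with
Lloyd-style k-means at its global optimum.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .metrics import METRIC_IDS, MetricVector

#: Metrics where smaller raw values are better (OO-style complexity metrics).
LOWER_BETTER = frozenset(
    {"LCOMOnto", "WMCOnto", "DITOnto", "NACOnto", "NOCOnto", "CBOnto",
     "RFCOnto", "NOMOnto", "TMOnto"}
)
#: Metrics where larger raw values are better; these are ratio metrics
#: expressed in percent on the static scale.
HIGHER_BETTER = frozenset({"RROnto", "AROnto", "INROnto", "CROnto", "ANOnto"})
PERCENT_METRICS = HIGHER_BETTER

# Static bin upper bounds, ascending.  For lower-is-better metrics the bins
# read: raw <= cuts[0] -> 5, (cuts[0], cuts[1]] -> 4, ..., raw > cuts[3] -> 1.
# For percent metrics: pct <= 20 -> 1, (20, 40] -> 2, ..., pct > 80 -> 5.
_STATIC_CUTS: dict[str, tuple[float, ...]] = {
    "LCOMOnto": (2, 4, 6, 8),
    "WMCOnto": (5, 8, 11, 15),
    "DITOnto": (2, 4, 6, 8),
    "NACOnto": (2, 4, 6, 8),
    "NOCOnto": (3, 6, 8, 12),
    "CBOnto": (2, 4, 6, 8),
    "RFCOnto": (3, 6, 8, 12),
    "NOMOnto": (2, 4, 6, 8),
    "TMOnto": (2, 4, 6, 8),
    "RROnto": (20, 40, 60, 80),
    "AROnto": (20, 40, 60, 80),
    "INROnto": (20, 40, 60, 80),
    "CROnto": (20, 40, 60, 80),
    "ANOnto": (20, 40, 60, 80),
}


def _check_metric(metric_id: str) -> None:
    if metric_id not in METRIC_IDS:
        raise KeyError(f"unknown metric id {metric_id!r}")


def static_score(metric_id: str, raw: float) -> int:
    """Score a raw metric value 1-5 on the fixed static scale.

    Percent-unit metrics are multiplied by 100 before binning; boundary
    values belong to the better bin.  Values beyond the extreme bins clamp
    to 1 or 5 (e.g. TMOnto fractions below the lowest printed bound clamp
    to 5).
    """
    _check_metric(metric_id)
    if not math.isfinite(raw) or raw < 0:
        raise ValueError(f"raw value for {metric_id} must be finite and >= 0, got {raw}")
    cuts = _STATIC_CUTS[metric_id]
    if metric_id in PERCENT_METRICS:
        return min(5, 1 + bisect_left(cuts, raw * 100.0))
    return max(1, 5 - bisect_left(cuts, raw))


class StaticScale:
    """The fixed scaling function, with the same interface as a fitted
    :class:`DynamicScale`."""

    name = "static"

    def score(self, metric_id: str, raw: float) -> int:
        return static_score(metric_id, raw)

    def __repr__(self):
        return "StaticScale()"


# ---------------------------------------------------------------------------
# exact 1-D k-means

def kmeans_1d(values: Sequence[float], k: int) -> list[list[float]]:
    """Partition ``values`` into ``k`` contiguous clusters minimising the
    within-cluster sum of squares (exact, via dynamic programming).

    Returns the clusters as lists of values in ascending order.  Ties between
    equal-cost partitions break toward the smaller split index, so the result
    is deterministic.
    """
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValueError("cannot cluster an empty value list")
    k = min(k, len(set(xs)))
    if k <= 0:
        raise ValueError("k must be positive")

    # prefix sums for O(1) segment cost
    pref = [0.0]
    pref2 = [0.0]
    for x in xs:
        pref.append(pref[-1] + x)
        pref2.append(pref2[-1] + x * x)

    def seg_cost(i: int, j: int) -> float:
        # SSE of xs[i:j]
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        m = j - i
        return max(0.0, s2 - s * s / m)

    INF = float("inf")
    # cost[c][j]: best cost of splitting xs[:j] into c clusters
    cost = [[INF] * (n + 1) for _ in range(k + 1)]
    split = [[0] * (n + 1) for _ in range(k + 1)]
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, c - 1
            for i in range(c - 1, j):
                if cost[c - 1][i] == INF:
                    continue
                cand = cost[c - 1][i] + seg_cost(i, j)
                if cand < best - 1e-12:
                    best, best_i = cand, i
            cost[c][j] = best
            split[c][j] = best_i
    # back-track
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c][j]
        bounds.append(j)
    bounds.reverse()
    return [xs[bounds[i]: bounds[i + 1]] for i in range(k)]


@dataclass
class DynamicScale:
    """Corpus-fitted scale: per metric, up to 5 closed raw-value intervals
    mapped to scores 1-5.  Low scores may be empty when the corpus shows
    fewer than 5 distinct values."""

    name = "dynamic"
    #: metric id -> {score: (low, high)} over the non-empty scores
    intervals: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)

    def score(self, metric_id: str, raw: float) -> int:
        return dynamic_score(self, metric_id, raw)

    def to_json(self, path=None) -> str:
        payload = {
            m: {str(s): list(iv) for s, iv in sorted(scores.items())}
            for m, scores in self.intervals.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "DynamicScale":
        try:
            payload = json.loads(text_or_path)
        except (ValueError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            intervals={
                m: {int(s): (iv[0], iv[1]) for s, iv in scores.items()}
                for m, scores in payload.items()
            }
        )


def fit_dynamic_scale(corpus_raw: dict[str, Sequence[float]], k: int = 5) -> DynamicScale:
    """Fit the dynamic scale to the raw values observed across a corpus.

    Each metric's values are clustered into ``min(k, #distinct)`` groups;
    clusters are ordered by the metric's direction so the best-valued cluster
    maps to score 5 and, when fewer than ``k`` clusters exist, the lowest
    scores stay empty.
    """
    intervals: dict[str, dict[int, tuple[float, float]]] = {}
    for metric_id, values in corpus_raw.items():
        _check_metric(metric_id)
        values = [v for v in values if v is not None]
        if not values:
            raise ValueError(f"no raw values for metric {metric_id}")
        clusters = kmeans_1d(values, k)
        n_clusters = len(clusters)
        per_metric: dict[int, tuple[float, float]] = {}
        for idx, cluster in enumerate(clusters):  # ascending raw value
            if metric_id in LOWER_BETTER:
                score = 5 - idx  # lowest cluster is best
            else:
                score = 5 - (n_clusters - 1 - idx)  # highest cluster is best
            per_metric[score] = (cluster[0], cluster[-1])
        intervals[metric_id] = per_metric
    return DynamicScale(intervals=intervals)


def dynamic_score(scale: DynamicScale, metric_id: str, raw: float) -> int:
    """Score a raw value on a fitted dynamic scale.

    Values inside a fitted interval take that interval's score; values
    outside every interval (unseen during fitting) clamp to the nearest
    interval, ties resolving to the better score.
    """
    _check_metric(metric_id)
    if metric_id not in scale.intervals:
        raise KeyError(f"metric {metric_id!r} was not fitted in this scale")
    best_score, best_dist = None, float("inf")
    for score, (lo, hi) in scale.intervals[metric_id].items():
        if lo <= raw <= hi:
            return score
        dist = (lo - raw) if raw < lo else (raw - hi)
        if dist < best_dist or (dist == best_dist and score > best_score):
            best_score, best_dist = score, dist
    return best_score


# ---------------------------------------------------------------------------
# score vectors

@dataclass
class ScoreVector:
    """The discretised quality scores of one version under one scale."""

    version: Optional[str]
    scores: dict[str, Optional[int]]
    scale: str  # "static" or "dynamic"

    @property
    def r(self) -> int:
        """Number of score components (the comparison-criteria dimension)."""
        return len(self.scores)

    def defined(self) -> dict[str, int]:
        return {m: s for m, s in self.scores.items() if s is not None}


def score_vector(
    m: MetricVector,
    scale: StaticScale | DynamicScale,
    version: Optional[str] = None,
) -> ScoreVector:
    """Apply a scaling function componentwise; undefined raw metrics yield
    undefined score components."""
    scores: dict[str, Optional[int]] = {}
    for metric_id in METRIC_IDS:
        raw = m[metric_id]
        scores[metric_id] = None if raw is None else scale.score(metric_id, raw)
    return ScoreVector(version=version, scores=scores, scale=scale.name)


def score_table(rows):
    """Score table: one row per version, one column per metric."""
    import pandas as pd

    return pd.DataFrame(
        [{"version": sv.version, **sv.scores} for sv in rows]
    ).set_index("version")
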