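"""Statistical ranking of version pairs and activity-vs-quality analysis.

Two questions are addressed.  First, which consecutive version pairs differ
most in raw metric values?  For each pair we take the 14 absolute raw-metric
differences and run a one-sided Wilcoxon signed-rank test of the alternative
that their median exceeds 0; pairs are ranked by the estimated median (the
"critical value") and p-value.  The exact null distribution is enumerated
for n <= 20 samples, with zero differences dropped and ties handled by
mid-ranks.

Second, how does quality change relate to editorial activity?  The three
dynamic-scale change statistics (backward size, forward size, mean change)
and the three activity variables (classes added / deleted / modified, the
Bubastis variables) enter a PCA on the correlation matrix; the first two
factors and the pairwise Pearson correlations summarise the relation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .evolution import ChangeStatistics, VersionedCorpus
from .metrics import METRIC_IDS
from .ontology_model import ActivityDelta


@dataclass(frozen=True)
class VersionTestResult:
    """Signed-rank test result for one version against its predecessor."""

    version: str
    estimate: float  # median of the absolute raw-metric differences
    p_value: Optional[float]  # None when the test is degenerate
    n: int  # number of non-zero differences entering the test
    degenerate: bool = False


def exact_signed_rank_p(diffs: Sequence[float]) -> Optional[float]:
    """One-sided p-value for the signed-rank test of median > 0.

    Zero differences are dropped; ties receive mid-ranks.  For n <= 20 the
    null distribution of the positive-rank sum is enumerated exactly by
    convolution; beyond that a normal approximation with tie correction is
    used.  Returns None when no non-zero difference remains.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return None
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 20:
        # convolve over 2*ranks so mid-ranks stay integral
        scaled = np.rint(2 * ranks).astype(int)
        total = scaled.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = 0.5 * (dist + shifted)
        target = int(math.ceil(round(2 * w_plus, 6)))
        return float(dist[target:].sum())
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_corr
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(sps.norm.sf(z))


def wilcoxon_consecutive(corpus: VersionedCorpus) -> list[VersionTestResult]:
    """Rank consecutive version pairs by significance of raw-metric change.

    For each pair, the absolute differences of the defined raw metrics are
    tested one-sided against a zero median; the estimate is the sample
    median of the absolute differences.  Results are sorted ascending by
    (estimate, p-value).  A pair with all-zero differences is flagged
    degenerate and carries no p-value.
    """
    if len(corpus) < 2:
        raise ValueError("need at least two processed versions")
    results = []
    for prev, nxt in zip(corpus.records, corpus.records[1:]):
        diffs = [
            abs(nxt.metrics[m] - prev.metrics[m])
            for m in METRIC_IDS
            if prev.metrics[m] is not None and nxt.metrics[m] is not None
        ]
        nonzero = [d for d in diffs if d != 0]
        estimate = float(np.median(diffs)) if diffs else 0.0
        if not nonzero:
            results.append(
                VersionTestResult(nxt.version, estimate, None, 0, degenerate=True)
            )
            continue
        p = exact_signed_rank_p(diffs)
        results.append(VersionTestResult(nxt.version, estimate, p, len(nonzero)))
    return sorted(results, key=lambda r: (r.estimate, r.p_value if r.p_value is not None else 2.0))


# ---------------------------------------------------------------------------
# PCA of change statistics against activity

PCA_VARIABLES = (
    "Number.New.Classes",
    "Number.Changed.Classes",
    "Number.Deleted.Classes",
    "Dynamic.Backward.Size",
    "Dynamic.Forward.Size",
    "Dynamic.Mean.Change",
)


@dataclass
class PCAResult:
    """Two-factor PCA of the standardised change/activity variables."""

    variables: tuple[str, ...]
    loadings: np.ndarray  # variables x 2, correlations with the factors
    explained_variance: tuple[float, ...]  # fraction per retained factor
    scores: np.ndarray  # versions x 2 factor scores
    dropped: tuple[str, ...] = ()


def pca_activity(
    change_stats: Sequence[ChangeStatistics],
    activity: Sequence[ActivityDelta],
) -> PCAResult:
    """Relate dynamic-scale change statistics to class-level activity.

    Builds the n_pairs x 6 matrix (new, changed, deleted, backward size,
    forward size, mean change), standardises each column, and performs a PCA
    on the correlation matrix.  Loadings are the correlations of the
    variables with the first two factors; constant variables are excluded
    with a warning.
    """
    if len(change_stats) != len(activity):
        raise ValueError("change statistics and activity lists differ in length")
    if len(change_stats) < 3:
        raise ValueError("need at least three version pairs for a PCA")
    X = np.array(
        [
            [
                a.n_new,
                a.n_changed,
                a.n_deleted,
                st.backward_size,
                st.forward_size,
                st.mean_change,
            ]
            for st, a in zip(change_stats, activity)
        ],
        dtype=float,
    )
    return _pca_correlation(X, PCA_VARIABLES)


def _pca_correlation(X: np.ndarray, names: Sequence[str]) -> PCAResult:
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(f"excluding constant variables from PCA: {dropped}", stacklevel=2)
    X = X[:, keep]
    kept_names = tuple(n for n, k in zip(names, keep) if k)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    n_factors = min(2, len(kept_names))
    loadings = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    # sign convention: the largest-magnitude loading of each factor is positive
    for j in range(n_factors):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            eigvec[:, j] *= -1
    scores = Z @ eigvec[:, :n_factors]
    explained = tuple(float(v) / len(kept_names) for v in eigval[:n_factors])
    return PCAResult(
        variables=kept_names,
        loadings=loadings,
        explained_variance=explained,
        scores=scores,
        dropped=dropped,
    )


def pearson_pairs(
    columns: dict[str, Sequence[float]],
) -> list[tuple[str, str, float, float]]:
    """Pearson correlation and p-value for every pair of variables."""
    names = list(columns)
    n_obs = {len(v) for v in columns.values()}
    if len(n_obs) != 1:
        raise ValueError("all variables must have the same number of observations")
    if n_obs.pop() < 3:
        raise ValueError("need at least three observations")
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = np.asarray(columns[a], float), np.asarray(columns[b], float)
            if xa.std() == 0 or xb.std() == 0:
                raise ValueError(f"constant column in Pearson test: {a if xa.std() == 0 else b}")
            r, p = sps.pearsonr(xa, xb)
            out.append((a, b, float(r), float(p)))
    return out


def wilcoxon_table(results: Sequence[VersionTestResult]):
    """Version ranking table (columns: Version, Critical_value, P_value)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "Version": r.version,
                "Critical_value": r.estimate,
                "P_value": "-" if r.p_value is None else r.p_value,
            }
            for r in results
        ]
    )


def pca_table(result: PCAResult):
    """Variable coordinates on the two retained factors."""
    import pandas as pd

    return pd.DataFrame(
        result.loadings,
        index=list(result.variables),
        columns=[f"Factor {j + 1}" for j in range(result.loadings.shape[1])],
    )
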