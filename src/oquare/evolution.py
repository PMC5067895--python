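"""Change-in-scale statistics over a versioned corpus.

Given the quality-score vectors of consecutive versions, the change in scale
is their componentwise difference (levels in [-4, 4]); its frequency
distribution counts how many metrics moved by each level.  From the
distribution come four statistics: the forward and backward mean changes
(weighted means of the positive / negative levels, undefined when no level
points that way), the global mean change, and the magnitude of change (the
percentage of metrics whose score changed at all).  The accumulative profile
is the running sum of mean changes across the life cycle.

Undefined directional means are a distinct ``None`` marker, not 0 and not an
exception, so report tables can print "-" for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .metrics import MetricVector
from .scaling import ScoreVector

L_MIN, L_MAX = -4, 4


@dataclass(frozen=True)
class ChangeVector:
    """Componentwise score difference between two consecutive versions."""

    levels: tuple[int, ...]

    def __post_init__(self):
        for l in self.levels:
            if not (L_MIN <= l <= L_MAX):
                raise ValueError(f"change level {l} outside [{L_MIN}, {L_MAX}]")

    @property
    def r(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class FrequencyDistribution:
    """Counts f_l of change levels l from -4 to 4 (9 components)."""

    counts: tuple[int, ...]  # ordered l = -4 .. 4

    def __post_init__(self):
        if len(self.counts) != L_MAX - L_MIN + 1:
            raise ValueError("frequency distribution must have 9 components")
        if any(c < 0 for c in self.counts):
            raise ValueError("frequencies must be non-negative")

    def __getitem__(self, level: int) -> int:
        if not (L_MIN <= level <= L_MAX):
            raise KeyError(level)
        return self.counts[level - L_MIN]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ChangeStatistics:
    """The four change statistics of one version pair (None = undefined)."""

    forward_mean: Optional[float]
    backward_mean: Optional[float]
    mean_change: float
    magnitude: float  # percent of metrics with a change in scale
    forward_size: float
    backward_size: float


def change_in_scale(prev: ScoreVector, next: ScoreVector) -> ChangeVector:
    """Componentwise integer difference next - prev of two score vectors.

    Both vectors must come from the same scale and have the same component
    set; components undefined in either vector are excluded.
    """
    if prev.scale != next.scale:
        raise ValueError(
            f"score vectors come from different scales: {prev.scale} vs {next.scale}"
        )
    if set(prev.scores) != set(next.scores):
        raise ValueError("score vectors have mismatched metric components")
    levels = [
        next.scores[m] - prev.scores[m]
        for m in prev.scores
        if prev.scores[m] is not None and next.scores[m] is not None
    ]
    return ChangeVector(levels=tuple(levels))


def frequency_distribution(l: ChangeVector) -> FrequencyDistribution:
    """Count the occurrences of each change level from -4 to 4."""
    counts = [0] * (L_MAX - L_MIN + 1)
    for level in l.levels:
        counts[level - L_MIN] += 1
    return FrequencyDistribution(counts=tuple(counts))


def change_statistics(F: FrequencyDistribution) -> ChangeStatistics:
    """Compute the four change statistics from a frequency distribution."""
    if F.total == 0:
        raise ValueError("empty frequency distribution")
    fwd_num = sum(l * F[l] for l in range(1, L_MAX + 1))
    fwd_den = sum(F[l] for l in range(1, L_MAX + 1))
    back_num = sum(l * F[l] for l in range(L_MIN, 0))
    back_den = sum(F[l] for l in range(L_MIN, 0))
    mean_change = sum(l * F[l] for l in range(L_MIN, L_MAX + 1)) / F.total
    magnitude = 100.0 * (F.total - F[0]) / F.total
    return ChangeStatistics(
        forward_mean=fwd_num / fwd_den if fwd_den else None,
        backward_mean=back_num / back_den if back_den else None,
        mean_change=mean_change,
        magnitude=magnitude,
        forward_size=float(fwd_num),
        backward_size=float(-back_num),
    )


def accumulative_profile(
    stats: Sequence[ChangeStatistics],
) -> list[float]:
    """Running sum of mean changes across the chronological life cycle."""
    profile = []
    acc = 0.0
    for st in stats:
        acc += st.mean_change
        profile.append(acc)
    return profile


# ---------------------------------------------------------------------------
# corpus container

@dataclass
class VersionRecord:
    """One processed version: identity, date and raw metric values."""

    version: str
    metrics: MetricVector
    date: Optional[str] = None


@dataclass
class VersionedCorpus:
    """Chronologically ordered list of processed versions of one ontology."""

    records: list[VersionRecord] = field(default_factory=list)

    def __post_init__(self):
        if len({r.version for r in self.records}) != len(self.records):
            raise ValueError("duplicate version identifiers in corpus")

    def __len__(self):
        return len(self.records)

    def raw_values(self) -> dict[str, list[Optional[float]]]:
        """Per-metric list of raw values across versions (fitting input)."""
        from .metrics import METRIC_IDS

        return {
            m: [r.metrics[m] for r in self.records] for m in METRIC_IDS
        }


def corpus_change_statistics(
    score_vectors: Sequence[ScoreVector],
) -> list[tuple[str, ChangeStatistics]]:
    """Change statistics for each version against the previous processed one.

    The first version has no predecessor and yields no entry; skipped
    (unprocessable) versions simply do not appear in ``score_vectors``, so
    each statistic is computed against the previous *processed* version.
    """
    out = []
    for prev, nxt in zip(score_vectors, score_vectors[1:]):
        F = frequency_distribution(change_in_scale(prev, nxt))
        out.append((nxt.version, change_statistics(F)))
    return out


def change_table(stats: Sequence[tuple[str, ChangeStatistics]]):
    """Change-statistics table (rows: magnitude / means; columns: versions).

    Undefined directional means print as "-".
    """
    import pandas as pd

    def fmt(v):
        return "-" if v is None else v

    data = {
        version: {
            "Magnitude": st.magnitude,
            "Mean. For": fmt(st.forward_mean),
            "Mean. Back": fmt(st.backward_mean),
            "Mean": st.mean_change,
        }
        for version, st in stats
    }
    return pd.DataFrame(data)
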