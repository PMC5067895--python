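"""Aggregation of metric scores into subcharacteristic and characteristic
quality scores.

The quality model is a two-level mapping in the SQuaRE tradition: each
*subcharacteristic* (e.g. Tangledness) is a weighted mean of the quality
scores of its associated metrics, and each *characteristic* (e.g.
Structural) is the unweighted mean of its subcharacteristics.  The overall
quality of a version is the mean of the characteristic scores.

The default configuration ships the published association subset; the full
49-subcharacteristic mapping is configurable through the same YAML format
(``subcharacteristics`` mapping names to ``{metric: weight}`` and
``characteristics`` mapping names to subcharacteristic lists).  Weights are
equal by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean
from typing import Optional

import yaml

from .metrics import METRIC_IDS
from .scaling import ScoreVector

#: Published subcharacteristic -> metric associations (equal weights).
_DEFAULT_SUBCHARACTERISTICS: dict[str, dict[str, float]] = {
    "Formal relations support": {"RROnto": 1},
    "Tangledness": {"TMOnto": 1},
    "Cohesion": {"LCOMOnto": 1},
    "Controlled vocabulary": {"ANOnto": 1},
    "Inference": {"RROnto": 1, "CROnto": 1},
    "Consistent search and query": {"ANOnto": 1, "RROnto": 1, "AROnto": 1, "INROnto": 1},
    "Knowledge acquisition and representation": {"ANOnto": 1, "RROnto": 1, "NOMOnto": 1},
    "Modularity": {"WMCOnto": 1, "CBOnto": 1},
    "Analysability": {
        "WMCOnto": 1, "DITOnto": 1, "RFCOnto": 1, "NOMOnto": 1, "LCOMOnto": 1, "CBOnto": 1,
    },
    "Modification stability": {
        "WMCOnto": 1, "NOCOnto": 1, "RFCOnto": 1, "LCOMOnto": 1, "CBOnto": 1,
    },
    "Recoverability": {"WMCOnto": 1, "DITOnto": 1, "NOMOnto": 1, "LCOMOnto": 1},
    "Availability": {"LCOMOnto": 1},
    "Learnability": {
        "WMCOnto": 1, "LCOMOnto": 1, "RFCOnto": 1, "NOMOnto": 1, "CBOnto": 1, "NOCOnto": 1,
    },
}

_DEFAULT_CHARACTERISTICS: dict[str, list[str]] = {
    "Structural": ["Formal relations support", "Tangledness", "Cohesion"],
    "Functional adequacy": [
        "Controlled vocabulary",
        "Inference",
        "Consistent search and query",
        "Knowledge acquisition and representation",
    ],
    "Maintainability": ["Modularity", "Analysability", "Modification stability"],
    "Reliability": ["Recoverability", "Availability"],
    "Operability": ["Learnability"],
}


@dataclass
class QualityModelConfig:
    """Configurable metric -> subcharacteristic -> characteristic mapping."""

    subcharacteristics: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in _DEFAULT_SUBCHARACTERISTICS.items()
        }
    )
    characteristics: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_CHARACTERISTICS.items()}
    )

    def __post_init__(self):
        for sub, weights in self.subcharacteristics.items():
            if not weights:
                raise ValueError(f"subcharacteristic {sub!r} maps to no metrics")
            for metric_id, w in weights.items():
                if metric_id not in METRIC_IDS:
                    raise ValueError(
                        f"subcharacteristic {sub!r} references unknown metric {metric_id!r}"
                    )
                if w <= 0:
                    raise ValueError(f"weight for {metric_id} in {sub!r} must be positive")
        for char, subs in self.characteristics.items():
            for sub in subs:
                if sub not in self.subcharacteristics:
                    raise ValueError(
                        f"characteristic {char!r} references unknown subcharacteristic {sub!r}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "QualityModelConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            subcharacteristics=payload["subcharacteristics"],
            characteristics=payload["characteristics"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "subcharacteristics": self.subcharacteristics,
                    "characteristics": self.characteristics,
                },
                fh,
                sort_keys=True,
            )


DEFAULT_MODEL = QualityModelConfig()


def subcharacteristic_scores(
    s: ScoreVector, cfg: QualityModelConfig = DEFAULT_MODEL
) -> dict[str, Optional[float]]:
    """Weighted mean of metric quality scores per subcharacteristic.

    Undefined metric scores drop out with re-normalised weights (and a
    warning); a subcharacteristic whose metrics are all undefined is
    reported as ``None``.
    """
    out: dict[str, Optional[float]] = {}
    for sub, weights in cfg.subcharacteristics.items():
        num = den = 0.0
        dropped = []
        for metric_id, w in weights.items():
            score = s.scores.get(metric_id)
            if score is None:
                dropped.append(metric_id)
                continue
            num += w * score
            den += w
        if dropped:
            warnings.warn(
                f"{sub}: dropping undefined metric scores {dropped} "
                "and re-normalising weights",
                stacklevel=2,
            )
        out[sub] = num / den if den else None
    return out


def characteristic_scores(
    sub: dict[str, Optional[float]], cfg: QualityModelConfig = DEFAULT_MODEL
) -> dict[str, Optional[float]]:
    """Unweighted mean of the constituent subcharacteristic scores."""
    out: dict[str, Optional[float]] = {}
    for char, subs in cfg.characteristics.items():
        defined = [sub[s] for s in subs if sub.get(s) is not None]
        out[char] = mean(defined) if defined else None
    return out


def overall_mean(char_scores: dict[str, Optional[float]]) -> Optional[float]:
    defined = [v for v in char_scores.values() if v is not None]
    return mean(defined) if defined else None


@dataclass
class QualityReport:
    """Aggregated quality scores of one version."""

    version: Optional[str]
    scale: str
    subcharacteristics: dict[str, Optional[float]]
    characteristics: dict[str, Optional[float]]
    overall: Optional[float]

    @classmethod
    def from_scores(
        cls, s: ScoreVector, cfg: QualityModelConfig = DEFAULT_MODEL
    ) -> "QualityReport":
        sub = subcharacteristic_scores(s, cfg)
        char = characteristic_scores(sub, cfg)
        return cls(
            version=s.version,
            scale=s.scale,
            subcharacteristics=sub,
            characteristics=char,
            overall=overall_mean(char),
        )

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "scale": self.scale,
            "subcharacteristics": self.subcharacteristics,
            "characteristics": self.characteristics,
            "overall": self.overall,
        }
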