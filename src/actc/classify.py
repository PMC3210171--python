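"""Threshold-box classifiers over the four object features.

A classifier is a named set of per-feature inclusion intervals; an object is
counted when every present rule holds.  Printed ``>`` / ``<`` bounds are
strict; range bounds are inclusive.  The built-in definitions are the optimal
automated CTC box, its reduced variants without the CD45 or DAPI criterion,
and the tumour-micro-particle (TMP) box for EpCAM+CK+CD45- objects under
4 µm equivalent-circle diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector


@dataclass(frozen=True)
class Rule:
    """One inclusion rule: strict greater-than, strict less-than, or an
    inclusive closed range."""

    gt: float | None = None
    lt: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        kinds = sum(x is not None for x in (self.gt, self.lt)) + (
            self.low is not None or self.high is not None
        )
        if kinds != 1:
            raise ValueError("rule must be exactly one of gt / lt / range")
        if self.low is not None or self.high is not None:
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError("range rule needs low <= high")

    def __call__(self, value: float) -> bool:
        if self.gt is not None:
            return value > self.gt
        if self.lt is not None:
            return value < self.lt
        return self.low <= value <= self.high

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.gt is not None:
            return values > self.gt
        if self.lt is not None:
            return values < self.lt
        return (values >= self.low) & (values <= self.high)

    def to_json(self) -> dict:
        if self.gt is not None:
            return {"gt": self.gt}
        if self.lt is not None:
            return {"lt": self.lt}
        return {"range": [self.low, self.high]}

    @classmethod
    def from_json(cls, obj: dict) -> "Rule":
        if "gt" in obj:
            return cls(gt=float(obj["gt"]))
        if "lt" in obj:
            return cls(lt=float(obj["lt"]))
        if "range" in obj:
            lo, hi = obj["range"]
            return cls(low=float(lo), high=float(hi))
        raise ValueError(f"unrecognised rule {obj!r}")


@dataclass(frozen=True)
class Classifier:
    """A named set of inclusion rules over feature space."""

    name: str
    rules: dict[str, Rule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("classifier needs at least one rule")
        unknown = set(self.rules) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")

    def without(self, feature: str, name: str | None = None) -> "Classifier":
        rules = {k: v for k, v in self.rules.items() if k != feature}
        return Classifier(name=name or f"{self.name}-no-{feature}", rules=rules)

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name,
             "rules": {k: r.to_json() for k, r in self.rules.items()}},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Classifier":
        obj = json.loads(text)
        return cls(
            name=obj["name"],
            rules={k: Rule.from_json(v) for k, v in obj["rules"].items()},
        )


# Built-in definitions.  The optimal automated-CTC box: CK-PE standard
# deviation >50 counts, size 75-500 pixels (34-224 µm²) inclusive, DAPI peak
# >170 counts, CD45 peak <60 counts.
OPTIMAL = Classifier(
    name="optimal",
    rules={
        "ck_std": Rule(gt=50),
        "size_px": Rule(low=75, high=500),
        "dapi_peak": Rule(gt=170),
        "cd45_peak": Rule(lt=60),
    },
)
NO_CD45 = OPTIMAL.without("cd45_peak", name="no-cd45")
NO_DAPI = OPTIMAL.without("dapi_peak", name="no-dapi")
TMP = Classifier(
    name="tmp",
    rules={
        "ck_std": Rule(gt=10),
        "cd45_peak": Rule(lt=60),
        "eq_diameter_um": Rule(lt=4),
    },
)

BUILTIN = {c.name: c for c in (OPTIMAL, NO_CD45, NO_DAPI, TMP)}


def classify_object(fv: FeatureVector, classifier: Classifier) -> bool:
    """True iff the object satisfies every rule of the classifier."""
    return all(rule(getattr(fv, feat)) for feat, rule in classifier.rules.items())


def classify_table(features: pd.DataFrame, classifier: Classifier) -> np.ndarray:
    """Vectorised classification of a feature table; returns a boolean mask."""
    mask = np.ones(len(features), dtype=bool)
    for feat, rule in classifier.rules.items():
        mask &= rule.apply(features[feat].to_numpy(dtype=float))
    return mask


def count_sample(
    objects: list[FeatureVector] | pd.DataFrame, classifier: Classifier
) -> int:
    """Number of objects in a sample satisfying the classifier."""
    if isinstance(objects, pd.DataFrame):
        return int(classify_table(objects, classifier).sum())
    return sum(classify_object(fv, classifier) for fv in objects)


def accepted_volume(
    classifier: Classifier, ranges: dict[str, tuple[float, float]]
) -> float:
    """Fraction of a reference feature box the classifier accepts.

    ``ranges`` gives the observed (min, max) per feature.  Features without a
    rule contribute factor 1; used as a strictness tie-break when comparing
    classifiers with equal objective score.
    """
    vol = 1.0
    for feat, (lo, hi) in ranges.items():
        span = max(hi - lo, np.finfo(float).tiny)
        rule = classifier.rules.get(feat)
        if rule is None:
            continue
        if rule.gt is not None:
            frac = (hi - max(rule.gt, lo)) / span
        elif rule.lt is not None:
            frac = (min(rule.lt, hi) - lo) / span
        else:
            frac = (min(rule.high, hi) - max(rule.low, lo)) / span
        vol *= min(max(frac, 0.0), 1.0)
    return vol
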