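"""Heart-rate-based physical workload scoring by Frimat's criterion.

Five cardiac indicators are computed from the heart rate stream and the
subject's age and resting heart rate:

* ACC, absolute cardiac cost: activity mean HR − resting HR (bpm), the
  intensity of a task;
* RCC, relative cardiac cost: ACC divided by the cardiac reserve
  HRmax − HRrest, the body's adaptation to the task (stored as a fraction);
* HRmax, theoretical maximum heart rate: 220 − age (bpm);
* HR̄, mean heart rate within the one-second evaluation window (bpm);
* ΔHR, cardiac acceleration: HRmax − HR̄ (bpm).

Each indicator maps to an integer coefficient 1–5 through fixed bins; the
coefficients sum to a score between 5 and 25, ranked qualitatively from
"Minimum workload" up to "Extremely hard".  Per-activity workload over a
session is the statistical mode of the per-second categories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import math

import pandas as pd

from .sensor_io import Session

__all__ = [
    "CATEGORIES",
    "INDICATOR_NAMES",
    "CardiacIndicators",
    "FrimatAssessment",
    "resting_hr",
    "compute_indicators",
    "coefficient_for",
    "frimat_score",
    "rank_score",
    "assess_window",
    "aggregate_activity_workload",
    "score_session",
]

#: Workload categories ordered from hardest to lightest.
CATEGORIES: tuple[str, ...] = (
    "Extremely hard",
    "Very hard",
    "Hard",
    "Distressing",
    "Bearable",
    "Light",
    "Very light",
    "Minimum workload",
)

INDICATOR_NAMES: tuple[str, ...] = ("acc", "rcc", "hr_max", "hr_mean", "delta_hr")

# Lower edges of the five coefficient bins per indicator.  Bins are
# half-open and integer-anchored: e.g. ACC in [20, 25) -> coefficient 3.
# Values below the lowest edge clamp to coefficient 1 (the score floor of 5
# requires every coefficient to be at least 1); values at or above the top
# edge map to 5.
_BIN_EDGES: dict[str, tuple[float, float, float, float, float]] = {
    "acc": (10.0, 15.0, 20.0, 25.0, 30.0),
    "rcc": (0.10, 0.15, 0.20, 0.25, 0.30),
    "hr_max": (110.0, 120.0, 130.0, 140.0, 150.0),
    "hr_mean": (90.0, 95.0, 100.0, 105.0, 110.0),
    "delta_hr": (20.0, 25.0, 30.0, 35.0, 40.0),
}

# Score -> category.  The published ranking skips 11; it is mapped to
# "Very light" (nearest band above) so the ranking stays monotone in score.
_SCORE_RANKING: dict[int, str] = {
    25: "Extremely hard",
    24: "Very hard",
    23: "Hard", 22: "Hard",
    21: "Distressing", 20: "Distressing",
    19: "Bearable", 18: "Bearable",
    17: "Light", 16: "Light", 15: "Light", 14: "Light",
    13: "Very light", 12: "Very light", 11: "Very light",
}
_SCORE_RANKING.update({s: "Minimum workload" for s in range(5, 11)})


@dataclass(frozen=True)
class CardiacIndicators:
    """The five cardiac indicators feeding Frimat's criterion.

    ``rcc`` is stored as a dimensionless fraction of the cardiac reserve.
    """

    acc: float
    rcc: float
    hr_max: float
    hr_mean: float
    delta_hr: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}


@dataclass(frozen=True)
class FrimatAssessment:
    """One window's workload assessment: coefficients, score and category."""

    indicators: CardiacIndicators
    coefficients: dict[str, int]
    score: int
    category: str


def resting_hr(hr_values: Sequence[float]) -> int:
    """Resting heart rate as the statistical mode of HR readings taken
    during resting periods.

    Values are rounded to the nearest integer bpm before the mode is taken;
    multimodal ties resolve to the smallest modal value (the conservative
    choice: a lower reference rate yields a higher cardiac cost).
    """
    values = list(hr_values)
    if not values:
        raise ValueError("resting_hr requires a non-empty list of HR values")
    if any(v <= 0 for v in values):
        raise ValueError("HR values must be positive")
    rounded = [int(math.floor(v + 0.5)) for v in values]
    counts = Counter(rounded)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def compute_indicators(
    hr_activity_mean: float,
    hr_rest: float,
    age: int,
    hr_window_mean: float,
) -> CardiacIndicators:
    """Compute the five cardiac indicators.

    ``hr_activity_mean`` is the average HR over the activity (drives ACC and
    RCC); ``hr_window_mean`` is the mean HR of the evaluation window (drives
    HR̄ and ΔHR).  For per-second assessment the two coincide.
    """
    if not (1 <= age <= 119):
        raise ValueError(f"age={age} outside 1..119")
    if hr_rest <= 0 or hr_activity_mean <= 0 or hr_window_mean <= 0:
        raise ValueError("heart rates must be positive")
    hr_max = 220.0 - age
    if hr_rest >= hr_max:
        raise ValueError(
            f"hr_rest={hr_rest} >= HRmax={hr_max}; cardiac reserve is degenerate"
        )
    acc = hr_activity_mean - hr_rest
    rcc = acc / (hr_max - hr_rest)
    return CardiacIndicators(
        acc=acc,
        rcc=rcc,
        hr_max=hr_max,
        hr_mean=hr_window_mean,
        delta_hr=hr_max - hr_window_mean,
    )


def coefficient_for(indicator: str, value: float) -> int:
    """Map an indicator value to its integer coefficient 1–5.

    ``rcc`` must be supplied as a fraction (e.g. 0.22, not 22).
    """
    if indicator not in _BIN_EDGES:
        raise ValueError(
            f"unknown indicator {indicator!r}; expected one of {INDICATOR_NAMES}"
        )
    if not math.isfinite(value):
        raise ValueError(f"indicator value must be finite, got {value}")
    edges = _BIN_EDGES[indicator]
    return 1 + sum(value >= e for e in edges[1:])


def frimat_score(coefficients: Mapping[str, int] | Sequence[int]) -> int:
    """Sum of the five coefficients; always in 5..25."""
    if isinstance(coefficients, Mapping):
        values = [coefficients[name] for name in INDICATOR_NAMES]
    else:
        values = list(coefficients)
    if len(values) != 5:
        raise ValueError(f"expected exactly five coefficients, got {len(values)}")
    for v in values:
        if v != int(v) or not (1 <= v <= 5):
            raise ValueError(f"coefficient {v!r} outside 1..5")
    return int(sum(values))


def rank_score(score: int) -> str:
    """Qualitative category for an integer score in 5..25."""
    if not (5 <= score <= 25):
        raise ValueError(f"score={score} outside 5..25")
    return _SCORE_RANKING[int(score)]


def assess_window(hr_window_mean: float, hr_rest: float, age: int) -> FrimatAssessment:
    """Full per-window assessment: indicators → coefficients → score → category.

    The window mean HR serves as the activity HR, matching per-second
    evaluation against a previously measured resting rate.
    """
    ind = compute_indicators(hr_window_mean, hr_rest, age, hr_window_mean)
    coefficients = {
        name: coefficient_for(name, value) for name, value in ind.as_dict().items()
    }
    score = frimat_score(coefficients)
    return FrimatAssessment(
        indicators=ind,
        coefficients=coefficients,
        score=score,
        category=rank_score(score),
    )


def aggregate_activity_workload(
    assessments: Iterable[FrimatAssessment | str],
) -> str:
    """Modal workload category over one activity segment.

    Accepts assessments or bare category strings.  Ties between equally
    frequent categories resolve to the harder one — conservative for worker
    protection.
    """
    categories = [
        a.category if isinstance(a, FrimatAssessment) else a for a in assessments
    ]
    if not categories:
        raise ValueError("cannot aggregate an empty list of assessments")
    for c in categories:
        if c not in CATEGORIES:
            raise ValueError(f"unknown workload category {c!r}")
    counts = Counter(categories)
    top = max(counts.values())
    modal = [c for c, n in counts.items() if n == top]
    return min(modal, key=CATEGORIES.index)


def score_session(
    session: Session,
    predicted_labels: Optional[Sequence[str]] = None,
    age: Optional[int] = None,
    hr_rest: Optional[float] = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-second workload report and per-activity modal summary.

    Each record's one-second mean HR is assessed against the subject's
    resting HR and age; rows are grouped by ``predicted_labels`` when given
    (the deployed behaviour — scoring follows the classifier), otherwise by
    the true labels.  Returns ``(report, summary)`` where ``report`` has one
    row per second and ``summary`` maps activity → modal category.
    """
    age = age if age is not None else session.age
    hr_rest = hr_rest if hr_rest is not None else session.hr_rest
    if age is None or hr_rest is None:
        raise ValueError("workload scoring requires subject age and resting HR")
    if predicted_labels is not None and len(predicted_labels) != len(session.records):
        raise ValueError("predicted_labels length must match record count")

    rows = []
    for i, rec in enumerate(session.records):
        if rec.mean_hr is None:
            raise ValueError(
                f"record at timestamp {rec.timestamp} has no mean HR; "
                "workload scoring needs HR on every second"
            )
        a = assess_window(rec.mean_hr, hr_rest, age)
        activity = predicted_labels[i] if predicted_labels is not None else rec.label
        row = {
            "timestamp": rec.timestamp,
            "activity": activity,
            "true_label": rec.label,
            "hr": rec.mean_hr,
            **{f"ind_{k}": v for k, v in a.indicators.as_dict().items()},
            **{f"coef_{k}": v for k, v in a.coefficients.items()},
            "score": a.score,
            "category": a.category,
        }
        rows.append(row)
    report = pd.DataFrame(rows)
    summary = {
        str(activity): aggregate_activity_workload(group["category"].tolist())
        for activity, group in report.groupby("activity")
    }
    return report, summary
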