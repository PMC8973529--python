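"""PH-FRAT part-1 risk scoring.

The Peninsula Health Falls Risk Assessment Tool (PH-FRAT) part 1 rates four
fall risk factors -- recent falls, medications, psychological status and
cognitive status -- on ordinal point scales and sums them to a total risk
score between 5 and 20.  A score strictly above a cut-off (14 in the
original instrument) classifies a resident as a likely faller; the
three-level grouping low/medium/high is used for care planning.

Only part 1 is modelled here: the risk-factor checklist (part 2) and action
plan (part 3) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "SCORE_MIN",
    "SCORE_MAX",
    "DEFAULT_CUTOFF",
    "RECENT_FALLS_MAX",
    "COMPONENT_LEVELS",
    "RISK_GROUP_BOUNDS",
    "PhfratComponents",
    "PhfratAssessment",
    "total_score",
    "classify",
    "risk_group",
]

SCORE_MIN = 5
SCORE_MAX = 20

#: Original instrument cut-off: > 14 likely faller, <= 14 non-faller.
DEFAULT_CUTOFF = 14

#: An in-facility fall within the past 3 months scores the maximum 8 points
#: on the recent-falls item.
RECENT_FALLS_MAX = 8

#: Admissible point levels per component.  Recent falls is weighted double
#: (2/4/6/8); the other three items score 1-4.  Minima sum to 5 and maxima
#: to 20, matching the tool's published total range.
COMPONENT_LEVELS: dict[str, tuple[int, ...]] = {
    "recent_falls_score": (2, 4, 6, 8),
    "medications_score": (1, 2, 3, 4),
    "psychological_score": (1, 2, 3, 4),
    "cognitive_score": (1, 2, 3, 4),
}

#: Closed integer score ranges of the three-level risk grouping.
RISK_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    "low": (5, 11),
    "medium": (12, 15),
    "high": (16, 20),
}


@dataclass(frozen=True)
class PhfratComponents:
    """The four ordinal item scores of one PH-FRAT administration."""

    recent_falls_score: int
    medications_score: int
    psychological_score: int
    cognitive_score: int

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            levels = COMPONENT_LEVELS[f.name]
            if value not in levels:
                raise ValueError(
                    f"{f.name}={value!r} is not an admissible level; "
                    f"expected one of {levels}"
                )

    def total(self) -> int:
        return (
            self.recent_falls_score
            + self.medications_score
            + self.psychological_score
            + self.cognitive_score
        )


@dataclass(frozen=True)
class PhfratAssessment:
    """One administration of the tool for one resident."""

    resident_id: str
    assessed_at: object  # datetime-like; pandas.Timestamp in practice
    components: PhfratComponents

    @property
    def total_score(self) -> int:
        return self.components.total()


def total_score(components: PhfratComponents) -> int:
    """Total risk score: the sum of the four item scores, in [5, 20]."""
    return components.total()


def classify(score: int, cutoff: int = DEFAULT_CUTOFF) -> bool:
    """Binary faller prediction: True iff ``score > cutoff`` (strict).

    The instrument's convention is strict: a score equal to the cut-off is
    a predicted non-faller.  ``cutoff`` must lie in [4, 20] so that both
    prediction classes are reachable at the extremes (cutoff 4 predicts
    everyone a faller, cutoff 20 nobody).
    """
    if not 4 <= cutoff <= 20:
        raise ValueError(f"cutoff must be in [4, 20], got {cutoff}")
    _check_score(score)
    return score > cutoff


def risk_group(score: int) -> str:
    """Three-level risk group label for a total score.

    low: 5-11, medium: 12-15, high: 16-20.
    """
    _check_score(score)
    for label, (lo, hi) in RISK_GROUP_BOUNDS.items():
        if lo <= score <= hi:
            return label
    raise AssertionError("unreachable: bounds partition [5, 20]")


def _check_score(score: int) -> None:
    if not float(score).is_integer():
        raise ValueError(f"total score must be an integer, got {score!r}")
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(
            f"total score {score} outside the instrument range "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )
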