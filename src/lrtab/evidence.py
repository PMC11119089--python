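"""Evidence grading on the support scale, and 2x2 effect sizes."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tables import ContingencyTable

__all__ = ["EvidenceGrade", "EffectSizes", "grade_support", "effect_sizes"]

# Half-open bands on |S|: lower bound -> label.  The scale's anchor points
# (1, 2, 3, 4, 7, 14) are read as lower bounds of the bands.
_BANDS: tuple[tuple[float, str], ...] = (
    (14.0, "million_to_one"),
    (7.0, "thousand_to_one"),
    (4.0, "extremely_strong"),
    (3.0, "strong"),
    (2.0, "moderate"),
    (1.0, "weak"),
    (0.0, "none"),
)

_LABEL_TEXT = {
    "none": "No evidence either way",
    "weak": "Weak evidence",
    "moderate": "Moderate evidence",
    "strong": "Strong evidence",
    "extremely_strong": "Extremely strong evidence",
    "thousand_to_one": "More than a thousand to one",
    "million_to_one": "More than a million to one",
}


@dataclass(frozen=True)
class EvidenceGrade:
    """A support value graded against the strength-of-evidence scale.

    direction is "H1" for positive S, "H2" for negative S (the evidence
    favours the second hypothesis), "none" at S = 0.
    """

    S: float
    likelihood_ratio: float
    label: str
    direction: str

    @property
    def description(self) -> str:
        return _LABEL_TEXT[self.label]

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "likelihood_ratio": self.likelihood_ratio,
            "label": self.label,
            "direction": self.direction,
            "description": self.description,
        }


@dataclass(frozen=True)
class EffectSizes:
    """Standard 2x2 effect sizes with rows as groups and column 1 the event.

    Risks are a/(a+b) and c/(c+d); the odds ratio is (a*d)/(b*c).  A zero
    cell makes the odds ratio 0 or infinite, signalled by has_zero_cell.
    """

    odds_ratio: float
    risk_ratio: float
    risk_difference: float
    log_odds_ratio: float
    has_zero_cell: bool

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "risk_ratio": self.risk_ratio,
            "risk_difference": self.risk_difference,
            "log_odds_ratio": self.log_odds_ratio,
            "has_zero_cell": self.has_zero_cell,
        }


def grade_support(S: float) -> EvidenceGrade:
    """Grade a support value S (finite or +/-inf) on the evidence scale."""
    if math.isnan(S):
        raise ValueError("S must not be NaN")
    mag = abs(S)
    label = "million_to_one" if math.isinf(mag) else next(
        lab for lo, lab in _BANDS if mag >= lo
    )
    if S > 0:
        direction = "H1"
    elif S < 0:
        direction = "H2"
    else:
        direction = "none"
    try:
        lr = math.exp(mag)
    except OverflowError:
        lr = math.inf
    return EvidenceGrade(S=S, likelihood_ratio=lr, label=label, direction=direction)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def effect_sizes(table: ContingencyTable) -> EffectSizes:
    """Odds ratio, risk ratio and risk difference for a 2x2 table."""
    if table.shape != (2, 2):
        raise ValueError(f"effect sizes require a 2x2 table, got {table.shape}")
    a, b = (int(x) for x in table.counts[0])
    c, d = (int(x) for x in table.counts[1])
    has_zero = 0 in (a, b, c, d)
    odds_ratio = _ratio(a * d, b * c)
    risk1 = _ratio(a, a + b)
    risk2 = _ratio(c, c + d)
    risk_ratio = _ratio(risk1, risk2)
    risk_difference = risk1 - risk2
    if odds_ratio == 0:
        log_or = -math.inf
    elif math.isinf(odds_ratio):
        log_or = math.inf
    elif math.isnan(odds_ratio):
        log_or = math.nan
    else:
        log_or = math.log(odds_ratio)
    return EffectSizes(
        odds_ratio=odds_ratio,
        risk_ratio=risk_ratio,
        risk_difference=risk_difference,
        log_odds_ratio=log_or,
        has_zero_cell=has_zero,
    )
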