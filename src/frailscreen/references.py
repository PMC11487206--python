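"""Clinical reference standards for frailty and falls-risk screening.

Scores and classifies the instruments used as reference standards:

* FRAIL scale — 5 items (Fatigue, Resistance = climbing one flight of
  stairs, Aerobic = walking 50 m, Illnesses >= 5, Loss of weight);
  score 0 = robust, 1-2 = prefrail, 3-5 = frail.  The functional split
  (fatigue/resistance/aerobic vs weight loss/illnesses) matches each
  wearable analyzer to what it can physically sense.
* SPPB — balance, gait and chair-stand components, 0-4 each, total 0-12,
  with a gait+balance-only subset (0-8).
* TUG — timed up and go, seconds.
* 4-m gait speed, m/s.
* FROP-Com — 13-factor falls-risk score, 0-60; <=11 low, 12-18 moderate,
  >=19 high.
* Fall history — a faller is anyone with >= 1 fall in the past 12 months.

``dichotomize`` converts each standard into a condition-positive /
condition-negative label for the 2x2 diagnostic framework.  The binary
cutpoints are not part of any instrument's definition; the defaults in
:class:`DichotomyConfig` are standard geriatric cutpoints and every rule
used is recorded in the emitted label for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, ScoringError

FRAIL_ITEM_NAMES = ("fatigue", "resistance", "aerobic", "illnesses", "weight_loss")
FUNCTIONAL_ITEMS = ("fatigue", "resistance", "aerobic")
NONFUNCTIONAL_ITEMS = ("weight_loss", "illnesses")


@dataclass(frozen=True)
class FrailItems:
    """The five FRAIL-scale items as booleans (deficit present)."""

    fatigue: bool
    resistance: bool
    aerobic: bool
    illnesses: bool
    weight_loss: bool


@dataclass
class ParticipantAssessment:
    """One participant's reference-standard assessment battery."""

    id: str
    frail_items: FrailItems
    sppb_gait: int
    sppb_balance: int
    sppb_chair: int
    tug_s: float
    gait_speed_mps: float
    frop_com: int
    falls_12mo: int
    adl_limit: bool = False
    iadl_limit: bool = False

    def __post_init__(self) -> None:
        for name in ("sppb_gait", "sppb_balance", "sppb_chair"):
            v = getattr(self, name)
            if not 0 <= v <= 4:
                raise ScoringError(f"{name}={v} outside the SPPB component range [0, 4]")
        if not 0 <= self.frop_com <= 60:
            raise ScoringError(f"frop_com={self.frop_com} outside [0, 60]")
        if self.tug_s <= 0:
            raise ScoringError(f"tug_s={self.tug_s} must be positive")
        if self.gait_speed_mps < 0:
            raise ScoringError(f"gait_speed_mps={self.gait_speed_mps} must be >= 0")
        if self.falls_12mo < 0:
            raise ScoringError(f"falls_12mo={self.falls_12mo} must be >= 0")

    def to_record(self) -> dict:
        rec = asdict(self)
        items = rec.pop("frail_items")
        rec.update({f"frail_{k}": v for k, v in items.items()})
        return rec


@dataclass
class ReferenceLabel:
    """Binary condition label derived from one reference standard."""

    standard: str
    condition_positive: bool
    detail: str
    rule: str


def _coerce_items(items) -> FrailItems:
    if isinstance(items, FrailItems):
        return items
    if isinstance(items, Mapping):
        for name in FRAIL_ITEM_NAMES:
            if name not in items:
                raise ScoringError(f"missing FRAIL item '{name}'")
        return FrailItems(**{k: bool(items[k]) for k in FRAIL_ITEM_NAMES})
    raise ScoringError("FRAIL items must be a FrailItems or a mapping of the five items")


def frail_classify(items) -> tuple[int, str]:
    """FRAIL score (count of deficits) and category.

    0 -> robust; 1-2 -> prefrail; 3-5 -> frail.
    """
    it = _coerce_items(items)
    score = sum(
        (it.fatigue, it.resistance, it.aerobic, it.illnesses, it.weight_loss)
    )
    if score == 0:
        category = "robust"
    elif score <= 2:
        category = "prefrail"
    else:
        category = "frail"
    return score, category


def frail_split(items) -> tuple[int, int]:
    """(functional, nonfunctional) FRAIL sub-scores.

    Functional = fatigue + resistance + aerobic (0-3); nonfunctional =
    weight loss + chronic illnesses (0-2).  Their sum is the full score.
    """
    it = _coerce_items(items)
    functional = int(it.fatigue) + int(it.resistance) + int(it.aerobic)
    nonfunctional = int(it.weight_loss) + int(it.illnesses)
    return functional, nonfunctional


def sppb_subset(assessment: ParticipantAssessment, subset: str = "total") -> int:
    """SPPB total (0-12) or the gait+balance subset (0-8)."""
    for name in ("sppb_gait", "sppb_balance", "sppb_chair"):
        v = getattr(assessment, name)
        if not 0 <= v <= 4:
            raise ScoringError(f"{name}={v} outside [0, 4]")
    if subset == "total":
        return assessment.sppb_gait + assessment.sppb_balance + assessment.sppb_chair
    if subset == "gait_balance":
        return assessment.sppb_gait + assessment.sppb_balance
    raise ConfigurationError(f"unknown SPPB subset {subset!r}")


def frop_com_class(score: int) -> str:
    """FROP-Com risk band: <=11 low, 12-18 moderate, >=19 high."""
    if not 0 <= score <= 60:
        raise ScoringError(f"FROP-Com score {score} outside [0, 60]")
    if score <= 11:
        return "low"
    if score <= 18:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class DichotomyConfig:
    """Binary cutpoints turning each standard into a 2x2 condition.

    Defaults are standard geriatric cutpoints; each is a free parameter
    because the framework treats the reference dichotomy as configuration.
    """

    sppb_total_max: int = 9          # impaired if total <= 9
    sppb_gait_balance_max: int = 6   # impaired if gait+balance <= 6
    gait_speed_min_mps: float = 0.8  # slow if speed < 0.8 m/s
    tug_max_s: float = 13.5          # at risk if TUG >= 13.5 s
    frail_total_min: int = 1         # positive if any FRAIL deficit
    frail_functional_min: int = 1
    frail_nonfunctional_min: int = 1
    frop_com_min: int = 12           # moderate-or-high falls risk
    faller_min_falls: int = 1


#: Reference-standard variants reported by the validation engine,
#: in presentation order.
STANDARDS = (
    "sppb_total",
    "sppb_gait_balance",
    "frail_total",
    "frail_functional",
    "frail_nonfunctional",
    "frop_com",
    "gait_speed",
    "tug",
)


def dichotomize(
    assessment: ParticipantAssessment,
    standard: str,
    config: DichotomyConfig | None = None,
) -> ReferenceLabel:
    """Condition-positive / negative label for one reference standard."""
    cfg = config or DichotomyConfig()
    if standard == "sppb_total":
        score = sppb_subset(assessment, "total")
        pos = score <= cfg.sppb_total_max
        return ReferenceLabel(standard, pos, f"score={score}",
                              f"total <= {cfg.sppb_total_max}")
    if standard == "sppb_gait_balance":
        score = sppb_subset(assessment, "gait_balance")
        pos = score <= cfg.sppb_gait_balance_max
        return ReferenceLabel(standard, pos, f"score={score}",
                              f"gait+balance <= {cfg.sppb_gait_balance_max}")
    if standard == "frail_total":
        score, category = frail_classify(assessment.frail_items)
        pos = score >= cfg.frail_total_min
        return ReferenceLabel(standard, pos, category,
                              f"score >= {cfg.frail_total_min}")
    if standard == "frail_functional":
        functional, _ = frail_split(assessment.frail_items)
        pos = functional >= cfg.frail_functional_min
        return ReferenceLabel(standard, pos, f"functional={functional}",
                              f"functional >= {cfg.frail_functional_min}")
    if standard == "frail_nonfunctional":
        _, nonfunctional = frail_split(assessment.frail_items)
        pos = nonfunctional >= cfg.frail_nonfunctional_min
        return ReferenceLabel(standard, pos, f"nonfunctional={nonfunctional}",
                              f"nonfunctional >= {cfg.frail_nonfunctional_min}")
    if standard == "frop_com":
        band = frop_com_class(assessment.frop_com)
        pos = assessment.frop_com >= cfg.frop_com_min
        return ReferenceLabel(standard, pos, band, f"score >= {cfg.frop_com_min}")
    if standard == "gait_speed":
        pos = assessment.gait_speed_mps < cfg.gait_speed_min_mps
        return ReferenceLabel(standard, pos, f"{assessment.gait_speed_mps:.2f} m/s",
                              f"speed < {cfg.gait_speed_min_mps}")
    if standard == "tug":
        pos = assessment.tug_s >= cfg.tug_max_s
        return ReferenceLabel(standard, pos, f"{assessment.tug_s:.1f} s",
                              f"tug >= {cfg.tug_max_s}")
    if standard == "faller":
        pos = assessment.falls_12mo >= cfg.faller_min_falls
        return ReferenceLabel(standard, pos, f"falls={assessment.falls_12mo}",
                              f"falls >= {cfg.faller_min_falls}")
    raise ConfigurationError(f"unknown reference standard {standard!r}")


def labels_frame(
    assessments: list[ParticipantAssessment],
    standards: tuple[str, ...] = STANDARDS,
    config: DichotomyConfig | None = None,
) -> pd.DataFrame:
    """Tidy labels table (`id,standard,condition_positive,detail,rule`)."""
    rows = []
    for a in assessments:
        for std in standards:
            lab = dichotomize(a, std, config)
            rows.append(
                {
                    "id": a.id,
                    "standard": lab.standard,
                    "condition_positive": lab.condition_positive,
                    "detail": lab.detail,
                    "rule": lab.rule,
                }
            )
    return pd.DataFrame(rows)
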