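"""Diagnostic-test validation: 2x2 tables, ROC, Youden cutoff, trapezoid AUC.

Each wearable screener statistic (gait risk score, HRR screener delta)
is validated against each clinical reference standard treated as the
condition definition.  For every screener x reference pair the engine

1. sweeps cutoffs over the screener scores (midpoints between sorted
   distinct values, plus +/-inf anchors, so strict/non-strict semantics
   are unambiguous),
2. computes sensitivity/specificity at each cutoff to form the ROC,
3. selects the optimal cutoff maximising the Youden index
   J = max(sensitivity + specificity - 1), and
4. computes the AUC as the sum of trapezoid areas between successive
   operating points — for a single interior operating point this equals
   (sensitivity + specificity) / 2.

The report mirrors the standard presentation of such validations: one
row per pair with the optimal cutoff, sensitivity, specificity,
TPR/FPR, PPV/NPV and AUC; structurally excluded pairs appear as
not-applicable rows.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"

#: Screener x reference pairs excluded from the report by design: the
#: gait analyzer senses only functional (movement) deficits and the
#: heart-rate analyzer only nonfunctional ones.
DEFAULT_EXCLUDED_PAIRS = frozenset(
    {
        ("gait_analyzer", "frail_nonfunctional"),
        ("heart_rate_analyzer", "frail_functional"),
    }
)


@dataclass(frozen=True)
class Contingency2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("2x2 counts must be nonnegative")
        if self.total < 1:
            raise ValidationError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticResult:
    """Operating-point statistics; ``None`` marks a zero-denominator cell."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    @property
    def tpr(self) -> float | None:
        return self.sensitivity

    @property
    def fpr(self) -> float | None:
        return None if self.specificity is None else 1.0 - self.specificity


@dataclass
class ROCCurve:
    """Operating points sorted by FPR, with (0,0) and (1,1) anchors."""

    cutoffs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    direction: str = HIGHER_IS_POSITIVE
    auc: float = field(init=False, default=float("nan"))
    optimal_cutoff: float = field(init=False, default=float("nan"))
    youden_j: float = field(init=False, default=float("nan"))

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.cutoffs.tolist(), self.fpr.tolist(), self.tpr.tolist()))


def contingency(
    screener_positive: Sequence[bool], condition: Sequence[bool]
) -> Contingency2x2:
    """Cross-tabulate screener outcome against the reference condition."""
    s = np.asarray(screener_positive, dtype=bool)
    c = np.asarray(condition, dtype=bool)
    if s.shape != c.shape or s.ndim != 1:
        raise ValidationError("screener and condition vectors must be equal-length 1-D")
    if s.size < 1:
        raise ValidationError("need at least one participant")
    return Contingency2x2(
        tp=int(np.sum(s & c)),
        fp=int(np.sum(s & ~c)),
        fn=int(np.sum(~s & c)),
        tn=int(np.sum(~s & ~c)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostics(c: Contingency2x2) -> DiagnosticResult:
    """Sensitivity, specificity, PPV and NPV from a 2x2 table.

    Zero-denominator statistics are reported as undefined (None), never
    coerced to 0 or 1.
    """
    return DiagnosticResult(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def roc_curve(
    screener_score: Sequence[float],
    condition: Sequence[bool],
    direction: str = HIGHER_IS_POSITIVE,
    name: str = "screener",
) -> ROCCurve:
    """ROC over all distinct-score cutoffs.

    A participant screens positive when score >= cutoff (for
    ``higher_is_positive``; the opposite direction negates scores
    internally).  Cutoffs are midpoints between sorted distinct scores
    plus +/-inf anchors, giving one operating point per achievable
    classification.
    """
    scores = np.asarray(screener_score, dtype=float)
    cond = np.asarray(condition, dtype=bool)
    if scores.shape != cond.shape or scores.ndim != 1:
        raise ValidationError("scores and condition must be equal-length 1-D vectors")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("screener scores must be finite")
    n_pos = int(cond.sum())
    n_neg = int(cond.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"condition vector for {name!r} has a single class "
            f"({n_pos} positive / {n_neg} negative); ROC undefined"
        )
    if direction == LOWER_IS_POSITIVE:
        work = -scores
    elif direction == HIGHER_IS_POSITIVE:
        work = scores
    else:
        raise ValidationError(f"unknown direction {direction!r}")

    distinct = np.unique(work)
    interior = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.empty(0)
    cuts = np.concatenate(([np.inf], interior[::-1], [-np.inf]))  # descending

    order = np.argsort(work, kind="stable")
    sorted_scores = work[order]
    pos_sorted = cond[order].astype(np.int64)
    cum_pos = np.concatenate(([0], np.cumsum(pos_sorted)))  # positives below index
    # number of scores < cutoff
    below = np.searchsorted(sorted_scores, cuts, side="left")
    pos_below = cum_pos[below]
    tp = n_pos - pos_below
    called_pos = scores.size - below
    fp = called_pos - tp
    tpr = tp / n_pos
    fpr = fp / n_neg

    out_cuts = -cuts if direction == LOWER_IS_POSITIVE else cuts
    roc = ROCCurve(cutoffs=out_cuts, fpr=fpr, tpr=tpr, direction=direction)
    roc.auc = auc_trapezoid(zip(fpr, tpr))
    roc.optimal_cutoff, roc.youden_j = youden_optimal(roc)
    return roc


def youden_optimal(roc: ROCCurve) -> tuple[float, float]:
    """Cutoff maximising J = TPR - FPR (= sensitivity + specificity - 1).

    Ties are broken toward the point with higher specificity (lower
    FPR), then toward the lower cutoff, so the choice is deterministic.
    """
    j = roc.tpr - roc.fpr
    if j.size == 0:
        raise ValidationError("empty ROC")
    best_j = float(j.max())
    candidates = np.where(j >= best_j - 1e-12)[0]
    best_fpr = roc.fpr[candidates].min()
    candidates = candidates[roc.fpr[candidates] <= best_fpr + 1e-12]
    cutoff = float(np.min(roc.cutoffs[candidates]))
    return cutoff, best_j


def auc_trapezoid(points: Iterable[tuple[float, float]]) -> float:
    """AUC as the sum of trapezoid areas between successive (FPR, TPR)
    points, sorted by FPR with (0,0)/(1,1) anchors added if absent."""
    pts = sorted({(float(f), float(t)) for f, t in points})
    if not pts or pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    area = 0.0
    for (f0, t0), (f1, t1) in zip(pts, pts[1:]):
        area += (f1 - f0) * (t0 + t1) / 2.0
    return float(area)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up (0.005 -> 0.01), matching printed-table conventions."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> int:
    """Whole-number percentage with half-up rounding (9/22 -> 41)."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return int(round_half_up(100.0 * numerator / denominator, 0))


@dataclass
class ScreenerScores:
    """Per-participant screener statistic; missing participants omitted."""

    name: str
    direction: str
    scores: Mapping[str, float]


REPORT_COLUMNS = [
    "screener",
    "reference",
    "n",
    "optimal_cutoff",
    "sensitivity",
    "specificity",
    "tpr",
    "fpr",
    "ppv",
    "npv",
    "auc",
    "youden_j",
    "note",
]


def validation_report(
    screeners: Sequence[ScreenerScores],
    reference_labels: Mapping[str, Mapping[str, bool]],
    excluded_pairs: frozenset[tuple[str, str]] = DEFAULT_EXCLUDED_PAIRS,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """One row per screener x reference pair (Table-2-style report).

    Participants missing a screener statistic are dropped pairwise; a
    screener covering less than ``min_coverage`` of the labelled cohort
    is an error.  Structurally excluded pairs and single-class
    conditions yield not-applicable rows with an explanatory note.
    """
    rows = []
    for scr in screeners:
        for ref_name, labels in reference_labels.items():
            row: dict = {c: np.nan for c in REPORT_COLUMNS}
            row.update(screener=scr.name, reference=ref_name, note="")
            if (scr.name, ref_name) in excluded_pairs:
                row["note"] = "not applicable (structural exclusion)"
                rows.append(row)
                continue
            ids = sorted(set(labels) & set(scr.scores))
            if len(labels) and len(ids) < min_coverage * len(labels):
                raise AnalysisError(
                    f"screener {scr.name!r} missing for more than "
                    f"{100 * (1 - min_coverage):.0f}% of the cohort "
                    f"({len(ids)}/{len(labels)} available)"
                )
            scores = np.array([scr.scores[i] for i in ids], dtype=float)
            cond = np.array([labels[i] for i in ids], dtype=bool)
            row["n"] = len(ids)
            try:
                roc = roc_curve(scores, cond, scr.direction, name=ref_name)
            except ValidationError as exc:
                row["note"] = f"not applicable ({exc})"
                rows.append(row)
                continue
            if scr.direction == LOWER_IS_POSITIVE:
                positive = scores <= roc.optimal_cutoff
            else:
                positive = scores >= roc.optimal_cutoff
            diag = diagnostics(contingency(positive, cond))
            row.update(
                optimal_cutoff=roc.optimal_cutoff,
                sensitivity=diag.sensitivity,
                specificity=diag.specificity,
                tpr=diag.tpr,
                fpr=diag.fpr,
                ppv=diag.ppv,
                npv=diag.npv,
                auc=roc.auc,
                youden_j=roc.youden_j,
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def format_report(report: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Display copy with rates rounded half-up to ``ndigits`` decimals."""
    out = report.copy()
    rate_cols = ["sensitivity", "specificity", "tpr", "fpr", "ppv", "npv", "auc", "youden_j"]
    for col in rate_cols:
        out[col] = [
            round_half_up(v, ndigits) if isinstance(v, float) and np.isfinite(v) else v
            for v in out[col]
        ]
    return out
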