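"""Gait analyzer: step detection, walking-bout segmentation and gait metrics.

Steps are detected as local maxima of the accelerometer vector magnitude
(orientation-independent for ankle placement) above a threshold, with a
refractory interval so one foot-strike yields one event.  Consecutive
steps separated by at most ``max_gap_s`` form a walking bout, and only
bouts of at least 40 continuous steps qualify for gait metrics — short
stop-start walking is too irregular to characterise free-living gait, so
qualifying bouts standardise the walking pattern.

The gait metrics are cadence plus fully specified proxies for gait
vigor: ``swing_power_proxy`` (mean squared magnitude deviation within
bout spans, g^2), ``toe_off_proxy`` (mean peak magnitude over steps, g),
and the step-time coefficient of variation.  An integer 0-5 risk score
counts impaired features and is the gait screener statistic fed to the
diagnostic validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InputFormatError
from .streams import AccelStream

#: Minimum run of continuous steps for a bout to qualify.
QUALIFYING_STEPS = 40

DEFAULT_MIN_PEAK_G = 1.25
DEFAULT_MIN_INTERVAL_S = 0.35
DEFAULT_MAX_GAP_S = 3.0


@dataclass(frozen=True)
class StepEvent:
    """A single detected step (time and magnitude of the peak)."""

    t_s: float
    peak_g: float


@dataclass
class WalkingBout:
    steps: list[StepEvent]
    n_steps: int
    cadence_sps: float  # (n_steps - 1) / bout span for n_steps >= 2
    qualifies: bool

    @property
    def t_start_s(self) -> float:
        return self.steps[0].t_s

    @property
    def t_end_s(self) -> float:
        return self.steps[-1].t_s


@dataclass
class GaitMetrics:
    mean_cadence_sps: float
    swing_power_proxy: float
    toe_off_proxy: float
    step_time_cv: float
    qualified_step_count: int

    def to_record(self) -> dict:
        return {
            "mean_cadence_sps": self.mean_cadence_sps,
            "swing_power_proxy": self.swing_power_proxy,
            "toe_off_proxy": self.toe_off_proxy,
            "step_time_cv": self.step_time_cv,
            "qualified_step_count": self.qualified_step_count,
        }


@dataclass
class GaitRiskScore:
    """Count of impaired gait features (0-5); the gait screener statistic."""

    score: int
    features_flagged: frozenset[str]


def detect_steps(
    accel: AccelStream,
    min_peak_g: float = DEFAULT_MIN_PEAK_G,
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
) -> list[StepEvent]:
    """Local maxima of the vector magnitude above ``min_peak_g``.

    Peaks closer than ``min_interval_s`` are suppressed keeping the
    larger one (refractory rule).  An empty stream yields an empty list.
    """
    if min_interval_s <= 0:
        raise InputFormatError("min_interval_s must be positive")
    if accel.n_samples == 0:
        return []
    vm = accel.magnitude()
    distance = max(1, int(round(min_interval_s * accel.rate_hz)))
    idx, _ = find_peaks(vm, height=min_peak_g, distance=distance)
    return [StepEvent(t_s=float(accel.t_s[i]), peak_g=float(vm[i])) for i in idx]


def segment_bouts(
    steps: list[StepEvent], max_gap_s: float = DEFAULT_MAX_GAP_S
) -> list[WalkingBout]:
    """Group time-ordered steps into bouts split at gaps > ``max_gap_s``.

    Every step belongs to exactly one bout; ``qualifies`` flags runs of
    at least 40 continuous steps.
    """
    if not steps:
        return []
    groups: list[list[StepEvent]] = [[steps[0]]]
    for prev, cur in zip(steps, steps[1:]):
        if cur.t_s - prev.t_s <= max_gap_s:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    bouts = []
    for g in groups:
        n = len(g)
        span = g[-1].t_s - g[0].t_s
        cadence = (n - 1) / span if n >= 2 and span > 0 else 0.0
        bouts.append(
            WalkingBout(steps=g, n_steps=n, cadence_sps=cadence,
                        qualifies=n >= QUALIFYING_STEPS)
        )
    return bouts


def compute_gait_metrics(
    bouts: list[WalkingBout], accel: AccelStream
) -> GaitMetrics | None:
    """Gait metrics over qualifying bouts, or None for insufficient data.

    Cadence is the step-count-weighted mean of bout cadences; the vigor
    proxies pool samples/steps across qualifying bouts.  Returning None
    (rather than raising) marks the participant "insufficient gait data"
    so downstream validation can exclude them explicitly.
    """
    qual = [b for b in bouts if b.qualifies]
    if not qual:
        return None
    weights = np.array([b.n_steps for b in qual], dtype=float)
    cadences = np.array([b.cadence_sps for b in qual])
    mean_cadence = float(np.average(cadences, weights=weights))

    dev = accel.deviation()
    sq_sum = 0.0
    n_sq = 0
    for b in qual:
        mask = (accel.t_s >= b.t_start_s) & (accel.t_s <= b.t_end_s)
        sq_sum += float(np.sum(dev[mask] ** 2))
        n_sq += int(np.count_nonzero(mask))
    swing_power = sq_sum / n_sq if n_sq else 0.0

    peaks = np.concatenate([[s.peak_g for s in b.steps] for b in qual])
    toe_off = float(np.mean(peaks))

    intervals = np.concatenate(
        [np.diff([s.t_s for s in b.steps]) for b in qual if b.n_steps >= 2]
    )
    if intervals.size and np.mean(intervals) > 0:
        step_time_cv = float(np.std(intervals) / np.mean(intervals))
    else:
        step_time_cv = 0.0

    return GaitMetrics(
        mean_cadence_sps=mean_cadence,
        swing_power_proxy=swing_power,
        toe_off_proxy=toe_off,
        step_time_cv=step_time_cv,
        qualified_step_count=int(weights.sum()),
    )


@dataclass(frozen=True)
class GaitThresholds:
    """Feature cutoffs for the 0-5 gait risk score.

    Cadence and step-time variability have literature norms and use
    absolute defaults; the device-specific vigor proxies and the step
    count default to cohort-relative (lowest-quartile) cutoffs computed
    by :func:`cohort_thresholds`.  A ``None`` cutoff disables its flag.
    """

    min_cadence_sps: float = 1.4
    max_step_time_cv: float = 0.10
    min_swing_power_g2: float | None = None
    min_toe_off_g: float | None = None
    min_qualified_steps: float | None = None


def cohort_thresholds(
    metrics: list[GaitMetrics | None],
    min_cadence_sps: float = 1.4,
    max_step_time_cv: float = 0.10,
    quantile: float = 0.25,
) -> GaitThresholds:
    """Cohort-relative cutoffs: lowest quartile of the vigor proxies."""
    avail = [m for m in metrics if m is not None]
    if not avail:
        return GaitThresholds(min_cadence_sps, max_step_time_cv)
    swing = np.quantile([m.swing_power_proxy for m in avail], quantile)
    toe = np.quantile([m.toe_off_proxy for m in avail], quantile)
    steps = np.quantile([m.qualified_step_count for m in avail], quantile)
    return GaitThresholds(
        min_cadence_sps=min_cadence_sps,
        max_step_time_cv=max_step_time_cv,
        min_swing_power_g2=float(swing),
        min_toe_off_g=float(toe),
        min_qualified_steps=float(steps),
    )


def gait_risk_score(
    metrics: GaitMetrics | None, thresholds: GaitThresholds | None = None
) -> GaitRiskScore | None:
    """Count impaired features; None metrics propagate to a missing score."""
    if metrics is None:
        return None
    th = thresholds or GaitThresholds()
    flags = set()
    if metrics.mean_cadence_sps < th.min_cadence_sps:
        flags.add("low_cadence")
    if metrics.step_time_cv > th.max_step_time_cv:
        flags.add("high_step_time_cv")
    if th.min_swing_power_g2 is not None and metrics.swing_power_proxy < th.min_swing_power_g2:
        flags.add("low_swing_power")
    if th.min_toe_off_g is not None and metrics.toe_off_proxy < th.min_toe_off_g:
        flags.add("low_toe_off")
    if th.min_qualified_steps is not None and metrics.qualified_step_count < th.min_qualified_steps:
        flags.add("low_step_count")
    return GaitRiskScore(score=len(flags), features_flagged=frozenset(flags))


def metrics_frame(metrics_by_id: dict[str, GaitMetrics | None]) -> pd.DataFrame:
    """Per-participant gait metrics table (NaN rows mark missing data)."""
    rows = []
    for pid, m in metrics_by_id.items():
        rec = {"id": pid}
        if m is None:
            rec.update({k: np.nan for k in GaitMetrics(0, 0, 0, 0, 0).to_record()})
            rec["insufficient_gait_data"] = True
        else:
            rec.update(m.to_record())
            rec["insufficient_gait_data"] = False
        rows.append(rec)
    return pd.DataFrame(rows)
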