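"""Daily living analyzer: epoch energy, intensity bands and daily kcal.

Energy per epoch is the mean squared deviation of the accelerometer
vector magnitude from the 1 g gravity baseline (units g^2) — the
standard accelerometry energy surrogate; it is zero at rest and scales
quadratically with movement amplitude.

Intensities are expressed relative to the participant's own walking
energy at a cadence of 1 step/second, so the bands are device- and
person-normalised:

* light (sitting):            intensity < 10 %
* moderate (household tasks): 10 % <= intensity < 30 %
* high (e.g. cycling):        intensity >= 30 %

Epoch energies aggregate into an estimated total daily energy in kcal
(basal term plus a configured conversion of intensity-weighted activity
hours), classified low (< 521), middle (521-770) or high (> 770)
kcal/day, with an hourly energy profile normalised to the day's maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .gait import WalkingBout
from .streams import AccelStream

LIGHT_MAX_PCT = 10.0
MODERATE_MAX_PCT = 30.0

KCAL_LOW_MAX = 521.0
KCAL_MIDDLE_MAX = 770.0

DEFAULT_EPOCH_S = 60.0
DEFAULT_BASAL_KCAL = 400.0
DEFAULT_KCAL_PER_PCT_HOUR = 2.8

SECONDS_PER_DAY = 86_400.0


@dataclass
class ActivityEpoch:
    t_start_s: float
    duration_s: float
    energy_raw: float                 # mean squared magnitude deviation, g^2
    intensity_pct: float | None = None  # % of the 1 step/s walking reference
    category: str | None = None         # light | moderate | high


@dataclass
class WalkingEnergyReference:
    """Epoch energy of walking at 1 step/second (g^2)."""

    e_ref: float
    source: str  # "measured-from-bouts" | "configured"


@dataclass
class DailyEnergySummary:
    date_index: int
    kcal: float
    kcal_class: str  # low | middle | high
    hourly_energy: np.ndarray  # 24-vector, max 1 on days with activity
    partial: bool = False


def epoch_energy(accel: AccelStream, epoch_s: float = DEFAULT_EPOCH_S) -> list[ActivityEpoch]:
    """Tile the recording into epochs and fill ``energy_raw``.

    A constant-gravity stream yields zero energy in every epoch.
    """
    if epoch_s <= 0:
        raise ConfigurationError("epoch_s must be positive")
    if accel.n_samples == 0:
        raise ConfigurationError("cannot compute epoch energy of an empty stream")
    if accel.rate_hz > 0 and epoch_s < 2.0 / accel.rate_hz:
        raise ConfigurationError(
            f"epoch of {epoch_s} s holds fewer than 2 samples at {accel.rate_hz} Hz"
        )
    t0 = accel.t_s[0]
    rel = accel.t_s - t0
    bins = np.floor(rel / epoch_s).astype(np.int64)
    dev_sq = accel.deviation() ** 2
    n_epochs = int(bins[-1]) + 1
    sums = np.bincount(bins, weights=dev_sq, minlength=n_epochs)
    counts = np.bincount(bins, minlength=n_epochs)
    t_end = accel.t_s[-1]
    epochs = []
    for i in range(n_epochs):
        start = t0 + i * epoch_s
        duration = min(epoch_s, t_end - start)
        energy = sums[i] / counts[i] if counts[i] else 0.0
        epochs.append(ActivityEpoch(t_start_s=float(start), duration_s=float(duration),
                                    energy_raw=float(energy)))
    return epochs


def walking_reference(
    accel: AccelStream,
    bouts: list[WalkingBout],
    fallback_e_ref: float | None = None,
) -> WalkingEnergyReference:
    """Walking energy rescaled to cadence 1 step/s.

    Pools the squared magnitude deviation over qualifying bout spans and
    divides by the (step-weighted) mean cadence squared — movement energy
    scales quadratically with cadence, so this maps the participant's
    observed walking to the 1 step/s reference.  Falls back to a
    configured value when no qualifying bout exists.
    """
    qual = [b for b in bouts if b.qualifies]
    if not qual:
        if fallback_e_ref is not None:
            if fallback_e_ref <= 0:
                raise ConfigurationError("fallback_e_ref must be positive")
            return WalkingEnergyReference(e_ref=float(fallback_e_ref), source="configured")
        raise AnalysisError(
            "no qualifying walking bout to measure the energy reference; "
            "configure fallback_e_ref"
        )
    dev_sq = accel.deviation() ** 2
    sq_sum = 0.0
    n = 0
    for b in qual:
        mask = (accel.t_s >= b.t_start_s) & (accel.t_s <= b.t_end_s)
        sq_sum += float(np.sum(dev_sq[mask]))
        n += int(np.count_nonzero(mask))
    if n == 0:
        raise AnalysisError("qualifying bouts contain no accelerometer samples")
    bout_energy = sq_sum / n
    weights = np.array([b.n_steps for b in qual], dtype=float)
    cadence = float(np.average([b.cadence_sps for b in qual], weights=weights))
    if cadence <= 0:
        raise AnalysisError("qualifying bouts have zero cadence")
    return WalkingEnergyReference(e_ref=bout_energy / cadence**2,
                                  source="measured-from-bouts")


def classify_intensity(intensity_pct: float) -> str:
    """Band for one intensity value; boundaries are exact (10 -> moderate,
    30 -> high)."""
    if intensity_pct < LIGHT_MAX_PCT:
        return "light"
    if intensity_pct < MODERATE_MAX_PCT:
        return "moderate"
    return "high"


def classify_epochs(
    epochs: list[ActivityEpoch], ref: WalkingEnergyReference
) -> list[ActivityEpoch]:
    """Fill ``intensity_pct`` (100 * energy / e_ref) and the band."""
    if ref.e_ref <= 0:
        raise ConfigurationError("walking energy reference must be positive")
    out = []
    for e in epochs:
        pct = 100.0 * e.energy_raw / ref.e_ref
        out.append(
            ActivityEpoch(
                t_start_s=e.t_start_s,
                duration_s=e.duration_s,
                energy_raw=e.energy_raw,
                intensity_pct=pct,
                category=classify_intensity(pct),
            )
        )
    return out


def classify_kcal(kcal: float) -> str:
    """Daily kcal band: low < 521, middle 521-770 (closed), high > 770."""
    if kcal < KCAL_LOW_MAX:
        return "low"
    if kcal <= KCAL_MIDDLE_MAX:
        return "middle"
    return "high"


def daily_summary(
    epochs: list[ActivityEpoch],
    basal_kcal: float = DEFAULT_BASAL_KCAL,
    kcal_per_pct_hour: float = DEFAULT_KCAL_PER_PCT_HOUR,
) -> list[DailyEnergySummary]:
    """Aggregate classified epochs into per-day energy summaries.

    kcal = basal + conversion * sum(intensity_pct * epoch hours); days
    covering less than a full 24 h of epochs are flagged partial but
    still summarised.  The hourly profile is normalised by the day's
    maximum hourly energy.
    """
    if kcal_per_pct_hour <= 0:
        raise ConfigurationError("kcal_per_pct_hour must be positive")
    if any(e.intensity_pct is None for e in epochs):
        raise ConfigurationError("epochs must be classified before daily_summary")
    by_day: dict[int, list[ActivityEpoch]] = {}
    for e in epochs:
        by_day.setdefault(int(math.floor(e.t_start_s / SECONDS_PER_DAY)), []).append(e)
    summaries = []
    for day in sorted(by_day):
        day_epochs = by_day[day]
        activity = sum(e.intensity_pct * e.duration_s / 3600.0 for e in day_epochs)
        kcal = basal_kcal + kcal_per_pct_hour * activity
        hourly = np.zeros(24)
        for e in day_epochs:
            hour = int((e.t_start_s - day * SECONDS_PER_DAY) // 3600) % 24
            hourly[hour] += e.intensity_pct * e.duration_s
        peak = hourly.max()
        if peak > 0:
            hourly = hourly / peak
        coverage = sum(e.duration_s for e in day_epochs)
        summaries.append(
            DailyEnergySummary(
                date_index=day,
                kcal=float(kcal),
                kcal_class=classify_kcal(kcal),
                hourly_energy=hourly,
                partial=coverage < SECONDS_PER_DAY * 0.999,
            )
        )
    return summaries


def epochs_frame(epochs: list[ActivityEpoch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_start_s": [e.t_start_s for e in epochs],
            "duration_s": [e.duration_s for e in epochs],
            "energy_raw": [e.energy_raw for e in epochs],
            "intensity_pct": [e.intensity_pct for e in epochs],
            "category": [e.category for e in epochs],
        }
    )


def summaries_frame(summaries: list[DailyEnergySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "date_index": [s.date_index for s in summaries],
            "kcal": [s.kcal for s in summaries],
            "kcal_class": [s.kcal_class for s in summaries],
            "partial": [s.partial for s in summaries],
        }
    )
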