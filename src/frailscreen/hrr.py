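"""Heart-rate analyzer: automated heart-rate-recovery (HRR) episodes.

A conventional HRR protocol needs a supervised graded-exercise bout; in
free living that is impractical, so exertion is found automatically from
the accelerometer-derived intensity series.  Each maximal run of
high-intensity epochs (>= 30 % of the walking reference) that contains
at least one heart-rate sample yields one episode: the peak HR within
the run is the maximum heart rate, and the next interval sample after
the peak is the recovered heart rate.  HRR = peak - recovered; larger
drops indicate better autonomic/cardiovascular fitness.

The screener statistic consumed by the diagnostic validation is the
*delta* (recovered - peak = -HRR), so that negative cutoffs such as -14
read "recovery smaller than 14 bpm screens positive".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy import ActivityEpoch
from .errors import ProtocolError
from .streams import HeartRateStream

logger = logging.getLogger(__name__)

#: Fraction of the sampling interval allowed beyond one interval when
#: locating the recovered sample (for jittered streams).
RECOVERY_TOLERANCE_FRAC = 0.10

_TIME_EPS = 1e-6


@dataclass
class HRREpisode:
    t_peak_s: float
    hr_max_bpm: float
    hr_recovered_bpm: float

    @property
    def hrr_bpm(self) -> float:
        return self.hr_max_bpm - self.hr_recovered_bpm

    @property
    def screener_delta_bpm(self) -> float:
        return -self.hrr_bpm


@dataclass
class ParticipantHRR:
    """Average HRR as the participant's singular measurement."""

    mean_hrr_bpm: float | None
    mean_screener_delta_bpm: float | None
    n_episodes: int

    @property
    def missing(self) -> bool:
        return self.n_episodes == 0


def _high_intensity_runs(epochs: list[ActivityEpoch]) -> list[tuple[float, float]]:
    """Maximal runs of time-contiguous high-intensity epochs as (start, end)."""
    runs: list[tuple[float, float]] = []
    current: tuple[float, float] | None = None
    for e in sorted(epochs, key=lambda x: x.t_start_s):
        if e.category is None:
            raise ProtocolError(
                "epochs carry no intensity categories; run classify_epochs first"
            )
        end = e.t_start_s + e.duration_s
        if e.category == "high":
            if current is not None and abs(e.t_start_s - current[1]) < _TIME_EPS:
                current = (current[0], end)
            else:
                if current is not None:
                    runs.append(current)
                current = (e.t_start_s, end)
        else:
            if current is not None:
                runs.append(current)
                current = None
    if current is not None:
        runs.append(current)
    return runs


def detect_episodes(
    hr: HeartRateStream,
    epochs: list[ActivityEpoch],
    tolerance_frac: float = RECOVERY_TOLERANCE_FRAC,
) -> list[HRREpisode]:
    """One HRR episode per high-intensity run containing a HR sample.

    The peak is the maximum HR sample within the run (earliest on ties,
    maximising the recovery window); the recovered value is the first
    sample strictly after the peak, provided it falls within one
    sampling interval (plus tolerance) of the peak.  Runs whose peak is
    the final recorded sample yield no episode.
    """
    if hr.n_samples == 0:
        return []
    runs = _high_intensity_runs(epochs)
    episodes = []
    max_lag = hr.interval_s * (1.0 + tolerance_frac)
    for start, end in runs:
        in_run = np.where((hr.t_s >= start) & (hr.t_s < end))[0]
        if in_run.size == 0:
            continue
        peak_local = int(np.argmax(hr.hr_bpm[in_run]))  # argmax -> earliest tie
        peak_idx = int(in_run[peak_local])
        next_idx = peak_idx + 1
        if next_idx >= hr.n_samples:
            continue  # no next sample exists
        if hr.t_s[next_idx] - hr.t_s[peak_idx] > max_lag:
            continue
        episodes.append(
            HRREpisode(
                t_peak_s=float(hr.t_s[peak_idx]),
                hr_max_bpm=float(hr.hr_bpm[peak_idx]),
                hr_recovered_bpm=float(hr.hr_bpm[next_idx]),
            )
        )
    return episodes


def average_hrr(episodes: list[HRREpisode]) -> ParticipantHRR:
    """Arithmetic mean of episode HRRs; zero episodes -> marked missing."""
    n = len(episodes)
    if n == 0:
        logger.info("no HRR episodes; participant excluded from validation")
        return ParticipantHRR(None, None, 0)
    mean_hrr = float(np.mean([e.hrr_bpm for e in episodes]))
    return ParticipantHRR(
        mean_hrr_bpm=mean_hrr, mean_screener_delta_bpm=-mean_hrr, n_episodes=n
    )


def episodes_frame(episodes: list[HRREpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_peak_s": [e.t_peak_s for e in episodes],
            "hr_max_bpm": [e.hr_max_bpm for e in episodes],
            "hr_recovered_bpm": [e.hr_recovered_bpm for e in episodes],
            "hrr_bpm": [e.hrr_bpm for e in episodes],
        }
    )
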