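"""Raw sensor stream containers.

The two physiological inputs of the pipeline are a triaxial ankle
accelerometer series (units of g, timestamps in seconds from recording
start) and an interval-sampled heart-rate series (bpm).  Both are thin
dataclasses over numpy arrays with CSV round-trip helpers; the CSV layouts
(``t_s,ax_g,ay_g,az_g`` and ``t_s,hr_bpm``) are the package's on-disk
interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError

GRAVITY_G = 1.0

HR_MIN_BPM = 30.0
HR_MAX_BPM = 220.0


@dataclass
class ActivityBout:
    """One scheduled activity segment in a synthetic recording.

    Generator bookkeeping: records what was injected (kind, span, step
    count and cadence for walking) so tests can use the schedule as an
    oracle for the analyzers.
    """

    kind: str  # "walk" | "moderate" | "exertion"
    t_start_s: float
    t_end_s: float
    n_steps: int = 0
    cadence_sps: float = 0.0
    step_times_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def _check_monotone(t: np.ndarray, what: str) -> None:
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InputFormatError(f"{what} timestamps must be strictly increasing")


@dataclass
class AccelStream:
    """Timestamped triaxial acceleration in g."""

    t_s: np.ndarray
    ax_g: np.ndarray
    ay_g: np.ndarray
    az_g: np.ndarray
    rate_hz: float
    schedule: list[ActivityBout] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.ax_g = np.asarray(self.ax_g, dtype=float)
        self.ay_g = np.asarray(self.ay_g, dtype=float)
        self.az_g = np.asarray(self.az_g, dtype=float)
        n = self.t_s.size
        if not (self.ax_g.size == self.ay_g.size == self.az_g.size == n):
            raise InputFormatError("accelerometer axes must have equal length")
        _check_monotone(self.t_s, "accelerometer")

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if self.n_samples else 0.0

    def magnitude(self) -> np.ndarray:
        """Orientation-independent vector magnitude sqrt(ax^2+ay^2+az^2)."""
        return np.sqrt(self.ax_g**2 + self.ay_g**2 + self.az_g**2)

    def deviation(self) -> np.ndarray:
        """Magnitude deviation from the 1 g gravity baseline."""
        return self.magnitude() - GRAVITY_G

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t_s, "ax_g": self.ax_g, "ay_g": self.ay_g, "az_g": self.az_g}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate_hz: float) -> "AccelStream":
        missing = {"t_s", "ax_g", "ay_g", "az_g"} - set(df.columns)
        if missing:
            raise InputFormatError(f"accelerometer CSV missing columns: {sorted(missing)}")
        return cls(
            t_s=df["t_s"].to_numpy(float),
            ax_g=df["ax_g"].to_numpy(float),
            ay_g=df["ay_g"].to_numpy(float),
            az_g=df["az_g"].to_numpy(float),
            rate_hz=rate_hz,
        )

    @classmethod
    def from_csv(cls, path, rate_hz: float | None = None) -> "AccelStream":
        df = pd.read_csv(path)
        if rate_hz is None:
            t = df["t_s"].to_numpy(float)
            dt = np.median(np.diff(t)) if t.size > 1 else 1.0
            rate_hz = 1.0 / dt if dt > 0 else 0.0
        return cls.from_frame(df, rate_hz)


@dataclass
class HeartRateStream:
    """Interval-sampled heart rate in bpm (default spacing 300 s)."""

    t_s: np.ndarray
    hr_bpm: np.ndarray
    interval_s: float = 300.0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.t_s.size != self.hr_bpm.size:
            raise InputFormatError("heart-rate times and values must have equal length")
        _check_monotone(self.t_s, "heart-rate")
        if self.hr_bpm.size and (
            self.hr_bpm.min() < HR_MIN_BPM or self.hr_bpm.max() > HR_MAX_BPM
        ):
            raise InputFormatError(
                f"heart-rate values must lie in [{HR_MIN_BPM:.0f}, {HR_MAX_BPM:.0f}] bpm"
            )

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t_s, "hr_bpm": self.hr_bpm})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, interval_s: float | None = None) -> "HeartRateStream":
        df = pd.read_csv(path)
        missing = {"t_s", "hr_bpm"} - set(df.columns)
        if missing:
            raise InputFormatError(f"heart-rate CSV missing columns: {sorted(missing)}")
        t = df["t_s"].to_numpy(float)
        if interval_s is None:
            interval_s = float(np.median(np.diff(t))) if t.size > 1 else 300.0
        return cls(t_s=t, hr_bpm=df["hr_bpm"].to_numpy(float), interval_s=interval_s)
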