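"""Shared fixtures: hand-built sensor streams independent of the cohort
generator, so analyzer tests have a ground truth that does not depend on
the code under test."""

from __future__ import annotations

import numpy as np
import pytest

from frailscreen.streams import AccelStream, HeartRateStream


def accel_from_deviation(dev: np.ndarray, rate_hz: float = 50.0) -> AccelStream:
    """Stream with a given vertical magnitude-deviation profile (az = 1 + dev)."""
    n = dev.size
    t = np.arange(n) / rate_hz
    return AccelStream(t_s=t, ax_g=np.zeros(n), ay_g=np.zeros(n),
                       az_g=1.0 + dev, rate_hz=rate_hz)


def impulse_train(
    n_steps: int,
    cadence_sps: float,
    amplitude_g: float = 0.6,
    impulse_s: float = 0.3,
    rate_hz: float = 50.0,
    lead_s: float = 2.0,
    trail_s: float = 2.0,
) -> tuple[AccelStream, np.ndarray]:
    """Raised-cosine step impulses at a fixed cadence; returns the stream
    and the exact impulse peak times (the step-detection oracle)."""
    duration = lead_s + n_steps / cadence_sps + trail_s
    n = int(round(duration * rate_hz))
    t = np.arange(n) / rate_hz
    dev = np.zeros(n)
    walking = (t >= lead_s) & (t < lead_s + n_steps / cadence_sps)
    tau = (t[walking] - lead_s) % (1.0 / cadence_sps)
    within = tau < impulse_s
    seg = np.zeros(walking.sum())
    seg[within] = amplitude_g * 0.5 * (1.0 - np.cos(2 * np.pi * tau[within] / impulse_s))
    dev[walking] = seg
    peak_times = lead_s + np.arange(n_steps) / cadence_sps + impulse_s / 2.0
    return accel_from_deviation(dev, rate_hz), peak_times


def hr_stream(values, interval_s: float = 300.0) -> HeartRateStream:
    values = np.asarray(values, dtype=float)
    return HeartRateStream(
        t_s=np.arange(values.size) * interval_s, hr_bpm=values, interval_s=interval_s
    )


@pytest.fixture
def flat_stream() -> AccelStream:
    """One minute of pure gravity (rest)."""
    return accel_from_deviation(np.zeros(3000), rate_hz=50.0)
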