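"""Synthetic older-adult cohort with wearable sensor streams.

Generates a seeded cohort whose statistical structure matches the study
conditions the analysis pipeline assumes: a robust/prefrail/frail mix of
0.41/0.45/0.14 at n = 22, walking bouts whose cadence tracks 4-m gait
speed, daily activity budgets spanning the three intensity bands, and
heart-rate dynamics in which frail participants have attenuated
heart-rate recovery (class means 25/17/10 bpm).

Each participant has a *latent* state (class, true HRR, true gait speed
and cadence, resting HR) behind the observables: a reference-standard
assessment battery drawn from class-conditional discrete distributions
(one ``assessment_noise`` knob controls FRAIL misclassification), a
triaxial ankle accelerometer stream, and an interval heart-rate stream.

Signal model (units: g, seconds, bpm):

* Gravity baseline of 1 g on the vertical axis plus white noise.
* Each step is a raised-cosine vertical impulse (amplitude encodes gait
  vigor via speed); a scheduled bout of n steps at cadence c injects
  exactly n impulses over n/c seconds.
* Moderate / exertion segments add sinusoidal magnitude oscillations
  whose amplitudes are set from the participant's analytic 1 step/s
  walking energy to land in the moderate (~18 %) and high (~60 %)
  intensity bands.
* Heart rate is sampled strictly periodically (default 300 s).  During
  walking/exertion segments HR ramps toward resting + gain; the first
  sample after the in-segment peak drops by the participant's true HRR
  plus noise, so the analyzer's episode protocol recovers the latent
  value (exactly at zero noise).

All randomness flows from the config seed; every generator returns
identical output for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .references import FrailItems, ParticipantAssessment, FRAIL_ITEM_NAMES
from .streams import AccelStream, ActivityBout, HeartRateStream, HR_MAX_BPM, HR_MIN_BPM

logger = logging.getLogger(__name__)

FRAILTY_CLASSES = ("robust", "prefrail", "frail")

SECONDS_PER_DAY = 86_400.0

#: Raised-cosine impulse: mean square over the impulse is (3/8) * amplitude^2.
_IMPULSE_MS_FACTOR = 3.0 / 8.0

_MIN_EVENT_GAP_S = 360.0  # rest between scheduled bouts; > one HR interval


@dataclass(frozen=True)
class ActivityBudget:
    """Daily minutes spent walking and in moderate / high-intensity activity."""

    walk_min: float
    moderate_min: float
    exertion_min: float


def _default_budgets() -> dict[str, ActivityBudget]:
    return {
        "robust": ActivityBudget(walk_min=60, moderate_min=120, exertion_min=45),
        "prefrail": ActivityBudget(walk_min=40, moderate_min=90, exertion_min=30),
        "frail": ActivityBudget(walk_min=20, moderate_min=60, exertion_min=20),
    }


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the reference cohort: n = 22 with a 41/45/14 %
    robust/prefrail/frail mix, heart rate sampled every 300 s, and
    class-separated true HRR (strictly decreasing robust -> frail).
    """

    n_participants: int = 22
    frailty_mix: tuple[float, float, float] = (0.41, 0.45, 0.14)
    hrr_means_bpm: tuple[float, float, float] = (25.0, 17.0, 10.0)
    hrr_sd_bpm: float = 4.0
    gait_speed_means_mps: tuple[float, float, float] = (1.05, 0.75, 0.45)
    gait_speed_sd_mps: float = 0.12
    activity_budget: dict[str, ActivityBudget] = field(default_factory=_default_budgets)
    accel_rate_hz: float = 50.0
    hr_interval_s: float = 300.0
    duration_days: float = 1.0
    seed: int = 0
    # noise knobs
    accel_noise_g: float = 0.02
    hr_noise_bpm: float = 2.0
    assessment_noise: float = 0.1
    cadence_jitter_sd: float = 0.05
    # physiology / signal-shape parameters
    resting_hr_mean_bpm: float = 72.0
    resting_hr_sd_bpm: float = 6.0
    exertion_gain_bpm: float = 50.0
    step_impulse_s: float = 0.30
    epoch_s: float = 60.0
    fallback_e_ref: float | None = None

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if len(self.frailty_mix) != 3 or any(p < 0 for p in self.frailty_mix):
            raise ConfigurationError("frailty_mix must be three nonnegative probabilities")
        if abs(sum(self.frailty_mix) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"frailty_mix must sum to 1 (got {sum(self.frailty_mix)!r})"
            )
        if not (self.hrr_means_bpm[0] > self.hrr_means_bpm[1] > self.hrr_means_bpm[2]):
            raise ConfigurationError(
                "hrr_means_bpm must be strictly decreasing from robust to frail"
            )
        if self.hr_interval_s <= 0:
            raise ConfigurationError("hr_interval_s must be positive")
        if self.accel_rate_hz < 20:
            raise ConfigurationError("accel_rate_hz must be at least 20 Hz")
        if self.duration_days < 1.0 / 24.0:
            raise ConfigurationError("duration_days must cover at least one hour")
        missing = set(FRAILTY_CLASSES) - set(self.activity_budget)
        if missing:
            raise ConfigurationError(f"activity_budget missing classes: {sorted(missing)}")

    def zero_noise(self) -> "CohortConfig":
        """Copy with all sensor/assessment noise removed (closure testing)."""
        return dataclasses.replace(
            self, accel_noise_g=0.0, hr_noise_bpm=0.0, assessment_noise=0.0,
            cadence_jitter_sd=0.0,
        )

    def to_json(self, path) -> None:
        data = dataclasses.asdict(self)
        data["activity_budget"] = {
            k: dataclasses.asdict(v) for k, v in self.activity_budget.items()
        }
        Path(path).write_text(json.dumps(data, indent=2))


@dataclass
class LatentParticipant:
    """Ground-truth state behind one participant's observables."""

    id: str
    frailty_class: str
    true_hrr_bpm: float
    true_gait_speed_mps: float
    true_cadence_sps: float
    resting_hr_bpm: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hrr_bpm < 0:
            raise ConfigurationError("true_hrr_bpm must be >= 0")
        if self.true_cadence_sps <= 0:
            raise ConfigurationError("true_cadence_sps must be positive")


def _cadence_from_speed(
    speed_mps: float, rng: np.random.Generator, jitter_sd: float
) -> float:
    """Cadence rises with gait speed (older-adult step lengths ~0.45-0.6 m)."""
    jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
    return float(np.clip(0.5 + 1.15 * speed_mps + jitter, 0.8, 2.4))


def _step_amplitude(speed_mps: float) -> float:
    """Step impulse amplitude (g above gravity); encodes gait vigor."""
    return float(min(0.7, 0.35 + 0.25 * speed_mps))


def analytic_e_ref(p: LatentParticipant, config: CohortConfig) -> float:
    """Expected measured walking reference for a synthetic participant.

    A bout at cadence c with impulse amplitude a has mean-square
    deviation (3/8) a^2 c T; rescaling by 1/c^2 gives the 1 step/s
    reference (3/8) a^2 T / c.
    """
    a = _step_amplitude(p.true_gait_speed_mps)
    return _IMPULSE_MS_FACTOR * a**2 * config.step_impulse_s / p.true_cadence_sps


# class-conditional discrete SPPB component distributions over scores 0-4,
# calibrated so the default-mix cohort means sit near 3.3 / 3.0 / 2.3
_SPPB_TABLES = {
    "gait": {
        "robust": (0.0, 0.0, 0.0, 0.3, 0.7),
        "prefrail": (0.0, 0.05, 0.15, 0.35, 0.45),
        "frail": (0.1, 0.3, 0.3, 0.2, 0.1),
    },
    "balance": {
        "robust": (0.0, 0.0, 0.1, 0.2, 0.7),
        "prefrail": (0.0, 0.1, 0.3, 0.3, 0.3),
        "frail": (0.2, 0.3, 0.3, 0.2, 0.0),
    },
    "chair": {
        "robust": (0.0, 0.1, 0.2, 0.4, 0.3),
        "prefrail": (0.1, 0.2, 0.3, 0.3, 0.1),
        "frail": (0.5, 0.3, 0.2, 0.0, 0.0),
    },
}

_TUG_PARAMS = {"robust": (9.0, 2.0), "prefrail": (14.0, 3.5), "frail": (28.0, 12.0)}
_FROP_PARAMS = {"robust": (8.0, 3.0), "prefrail": (14.0, 3.0), "frail": (22.0, 4.0)}
_FALL_PROB = {"robust": 0.20, "prefrail": 0.45, "frail": 0.60}
_ADL_PROB = {"robust": 0.05, "prefrail": 0.20, "frail": 0.50}

_FRAIL_BANDS = {"robust": (0, 0), "prefrail": (1, 2), "frail": (3, 5)}
_NEIGHBOR_BAND = {"robust": ("prefrail",), "prefrail": ("robust", "frail"),
                  "frail": ("prefrail",)}


def _draw_frail_items(rng: np.random.Generator, cls: str, noise: float) -> FrailItems:
    band_cls = cls
    if noise > 0 and rng.random() < noise:
        neighbors = _NEIGHBOR_BAND[cls]
        band_cls = neighbors[int(rng.integers(len(neighbors)))]
    lo, hi = _FRAIL_BANDS[band_cls]
    score = int(rng.integers(lo, hi + 1))
    chosen = rng.permutation(5)[:score]
    flags = {name: (i in chosen) for i, name in enumerate(FRAIL_ITEM_NAMES)}
    return FrailItems(**flags)


def _draw_assessment(
    rng: np.random.Generator, p: LatentParticipant, config: CohortConfig
) -> ParticipantAssessment:
    cls = p.frailty_class
    items = _draw_frail_items(rng, cls, config.assessment_noise)
    sppb = {
        comp: int(rng.choice(5, p=table[cls]))
        for comp, table in _SPPB_TABLES.items()
    }
    mu, sd = _TUG_PARAMS[cls]
    tug = float(max(3.4, rng.normal(mu, sd)))
    mu, sd = _FROP_PARAMS[cls]
    frop = int(np.clip(round(rng.normal(mu, sd)), 0, 60))
    faller = rng.random() < _FALL_PROB[cls]
    falls = int(1 + rng.poisson(0.5)) if faller else 0
    return ParticipantAssessment(
        id=p.id,
        frail_items=items,
        sppb_gait=sppb["gait"],
        sppb_balance=sppb["balance"],
        sppb_chair=sppb["chair"],
        tug_s=tug,
        gait_speed_mps=float(
            max(0.1, p.true_gait_speed_mps
                + rng.normal(0.0, 0.3 * config.assessment_noise))
            if config.assessment_noise > 0 else p.true_gait_speed_mps
        ),
        frop_com=frop,
        falls_12mo=falls,
        adl_limit=bool(rng.random() < _ADL_PROB[cls]),
        iadl_limit=bool(rng.random() < _ADL_PROB[cls]),
    )


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[LatentParticipant, ParticipantAssessment]]:
    """Draw the cohort: latent participants plus assessment batteries."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.frailty_mix, dtype=float)
    classes = rng.choice(3, size=config.n_participants, p=mix / mix.sum())
    cohort = []
    for i, ci in enumerate(classes):
        cls = FRAILTY_CLASSES[int(ci)]
        speed = float(max(0.2, rng.normal(config.gait_speed_means_mps[ci],
                                          config.gait_speed_sd_mps)))
        cadence = _cadence_from_speed(speed, rng, config.cadence_jitter_sd)
        hrr = float(max(0.0, rng.normal(config.hrr_means_bpm[ci], config.hrr_sd_bpm)))
        resting = float(np.clip(rng.normal(config.resting_hr_mean_bpm,
                                           config.resting_hr_sd_bpm), 50.0, 100.0))
        p = LatentParticipant(
            id=f"P{i:03d}",
            frailty_class=cls,
            true_hrr_bpm=hrr,
            true_gait_speed_mps=speed,
            true_cadence_sps=cadence,
            resting_hr_bpm=resting,
            seed=int(rng.integers(2**31 - 1)),
        )
        cohort.append((p, _draw_assessment(rng, p, config)))
    return cohort


def _build_schedule(
    p: LatentParticipant, config: CohortConfig, rng: np.random.Generator
) -> list[ActivityBout]:
    """Lay out walking / moderate / exertion bouts over the recording.

    Bouts are interleaved in a seeded random order with equal rest gaps
    of at least one HR interval, so recovery samples never collide with
    the next exertion segment.  Exertion bouts are aligned to the epoch
    grid.  Walking includes one deliberately short (25-step) bout so
    both non-qualifying and qualifying runs occur.
    """
    duration_s = config.duration_days * SECONDS_PER_DAY
    budget = config.activity_budget[p.frailty_class]
    c = p.true_cadence_sps
    events: list[tuple[str, float, int]] = []  # (kind, duration_s, n_steps)

    walk_s = budget.walk_min * 60.0 * config.duration_days
    if walk_s > 0:
        short_steps = 25
        short_dur = short_steps / c
        if walk_s > 2 * short_dur:
            events.append(("walk", short_dur, short_steps))
            walk_s -= short_dur
        n_long = max(1, int(round(walk_s / 240.0)))
        per = walk_s / n_long
        for _ in range(n_long):
            steps = max(40, int(round(per * c)))
            events.append(("walk", steps / c, steps))

    mod_s = budget.moderate_min * 60.0 * config.duration_days
    if mod_s > 0:
        n_mod = max(1, int(round(mod_s / 900.0)))
        for _ in range(n_mod):
            events.append(("moderate", mod_s / n_mod, 0))

    ex_s = budget.exertion_min * 60.0 * config.duration_days
    if ex_s > 0:
        n_ex = max(1, int(round(ex_s / 600.0)))
        per = max(2 * config.epoch_s,
                  round((ex_s / n_ex) / config.epoch_s) * config.epoch_s)
        for _ in range(n_ex):
            events.append(("exertion", per, 0))

    # drop events (longest first) until bouts plus minimum gaps fit
    def _fits() -> bool:
        busy = sum(d for _, d, _ in events)
        slack = (len(events) + 1) * _MIN_EVENT_GAP_S + len(events) * config.epoch_s
        return busy + slack <= duration_s

    while events and not _fits():
        events.pop(int(np.argmax([d for _, d, _ in events])))

    if not events:
        return []
    order = rng.permutation(len(events))
    busy = sum(d for _, d, _ in events)
    gap = (duration_s - busy - len(events) * config.epoch_s) / (len(events) + 1)
    schedule: list[ActivityBout] = []
    t = gap
    for idx in order:
        kind, dur, n_steps = events[idx]
        start = t
        if kind == "exertion":  # align to the epoch grid for clean high runs
            start = math.ceil(start / config.epoch_s) * config.epoch_s
        end = start + dur
        if end > duration_s:
            break
        bout = ActivityBout(kind=kind, t_start_s=start, t_end_s=end,
                            n_steps=n_steps, cadence_sps=c if n_steps else 0.0)
        if kind == "walk":
            bout.step_times_s = start + np.arange(n_steps) / c + config.step_impulse_s / 2
        schedule.append(bout)
        t = end + gap
    return schedule


def generate_accel_stream(p: LatentParticipant, config: CohortConfig) -> AccelStream:
    """Synthesize the triaxial accelerometer stream for one participant."""
    config.validate()
    duration_s = config.duration_days * SECONDS_PER_DAY
    rng = np.random.default_rng([p.seed, 1])
    schedule = _build_schedule(p, config, rng)

    n = int(round(duration_s * config.accel_rate_hz))
    t = np.arange(n) / config.accel_rate_hz
    noise = config.accel_noise_g
    ax = rng.normal(0.0, noise, n) if noise > 0 else np.zeros(n)
    ay = rng.normal(0.0, noise, n) if noise > 0 else np.zeros(n)
    az = 1.0 + (rng.normal(0.0, noise, n) if noise > 0 else np.zeros(n))

    a_step = _step_amplitude(p.true_gait_speed_mps)
    e_ref = analytic_e_ref(p, config)
    amp_mod = math.sqrt(2 * 0.18 * e_ref)
    amp_high = min(0.24, math.sqrt(2 * 0.60 * e_ref))
    T = config.step_impulse_s

    for bout in schedule:
        i0 = int(np.searchsorted(t, bout.t_start_s, side="left"))
        i1 = int(np.searchsorted(t, bout.t_end_s, side="left"))
        seg = t[i0:i1] - bout.t_start_s
        if seg.size == 0:
            continue
        if bout.kind == "walk":
            tau = seg % (1.0 / bout.cadence_sps)
            within = tau < T
            az[i0:i1][within] += a_step * 0.5 * (1.0 - np.cos(2 * np.pi * tau[within] / T))
        elif bout.kind == "moderate":
            az[i0:i1] += amp_mod * np.sin(2 * np.pi * 1.1 * seg)
        else:  # exertion
            az[i0:i1] += amp_high * np.sin(2 * np.pi * 1.6 * seg)

    return AccelStream(t_s=t, ax_g=ax, ay_g=ay, az_g=az,
                       rate_hz=config.accel_rate_hz, schedule=schedule)


def generate_hr_stream(
    p: LatentParticipant, accel: AccelStream, config: CohortConfig
) -> HeartRateStream:
    """Synthesize the interval heart-rate stream on the accel time base.

    Walking and exertion segments (both exceed the 30 % intensity band)
    drive HR toward resting + gain; the sample following each segment's
    peak drops by the participant's true HRR plus noise.
    """
    if accel.n_samples == 0:
        logger.warning("empty accelerometer stream for %s; emitting empty HR stream", p.id)
        return HeartRateStream(t_s=np.empty(0), hr_bpm=np.empty(0),
                               interval_s=config.hr_interval_s)
    rng = np.random.default_rng([p.seed, 2])
    duration_s = config.duration_days * SECONDS_PER_DAY
    times = np.arange(0.0, duration_s, config.hr_interval_s)
    noise = config.hr_noise_bpm
    hr = p.resting_hr_bpm + (rng.normal(0.0, noise, times.size) if noise > 0
                             else np.zeros(times.size))

    segments = sorted(
        (b for b in (accel.schedule or []) if b.kind in ("walk", "exertion")),
        key=lambda b: b.t_start_s,
    )
    epoch = config.epoch_s
    for b in segments:
        # expand to the epoch grid: partially covered epochs still classify
        # as high intensity, so the analyzer's run spans whole epochs
        w0 = math.floor(b.t_start_s / epoch) * epoch
        w1 = math.ceil(b.t_end_s / epoch) * epoch
        in_idx = np.where((times >= w0) & (times < w1))[0]
        if in_idx.size == 0:
            continue
        gain = config.exertion_gain_bpm * (1.0 if b.kind == "exertion" else 0.6)
        ramp = p.resting_hr_bpm + gain * np.arange(1, in_idx.size + 1) / in_idx.size
        if noise > 0:
            ramp = np.sort(ramp + rng.normal(0.0, noise, in_idx.size))
        hr[in_idx] = ramp
        nxt = int(in_idx[-1]) + 1
        if nxt < times.size:
            drop = p.true_hrr_bpm + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            hr[nxt] = ramp[-1] - drop
    hr = np.clip(hr, HR_MIN_BPM, HR_MAX_BPM)
    return HeartRateStream(t_s=times, hr_bpm=hr, interval_s=config.hr_interval_s)


def cohort_frame(
    cohort: list[tuple[LatentParticipant, ParticipantAssessment]]
) -> pd.DataFrame:
    """One row per participant: latent state plus assessment fields."""
    rows = []
    for p, a in cohort:
        rec = {
            "id": p.id,
            "frailty_class": p.frailty_class,
            "true_hrr_bpm": p.true_hrr_bpm,
            "true_gait_speed_mps": p.true_gait_speed_mps,
            "true_cadence_sps": p.true_cadence_sps,
            "resting_hr_bpm": p.resting_hr_bpm,
        }
        rec.update({k: v for k, v in a.to_record().items() if k != "id"})
        rows.append(rec)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: list[tuple[LatentParticipant, ParticipantAssessment]],
    config: CohortConfig,
    out_dir,
) -> None:
    """Write the cohort CSV plus a JSON sidecar with the generating config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_frame(cohort).to_csv(out / "cohort.csv", index=False)
    config.to_json(out / "config.json")
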