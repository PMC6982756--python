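"""Synthetic wearable sessions for the five-activity fitness routine.

The generator emulates the signals the pipeline consumes — hip-worn 20 Hz
triaxial accelerometry in units of g plus a 1 Hz mean heart rate — for the
activities resting, crunches, push-ups, squatting and jogging.

Accelerometer model per activity: a posture-dependent gravity projection
plus a single sinusoid (the dominant movement component) plus white
Gaussian noise, clipped to the ±2 g sensor full scale.  Postures give the
static contrast (upright vs prone vs supine); oscillation frequency and
amplitude give the dynamic contrast (fast large strides vs slow squats).

Heart rate follows a first-order relaxation toward an activity-specific
target: HR(t+1) = HR(t) + (target − HR(t))/τ + noise, started from the
subject's resting rate.  τ defaults to 20 s, a plausible exercise-onset
time constant; HR noise defaults to 1.5 bpm.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .sensor_io import (
    ACCEL_FULL_SCALE_G,
    ACTIVITIES,
    SAMPLES_PER_SECOND,
    AccelSample,
    SecondRecord,
    Session,
)

__all__ = [
    "ActivityModel",
    "SessionScript",
    "default_activity_models",
    "default_script",
    "generate_accel_stream",
    "generate_hr_stream",
    "generate_session",
    "load_models_config",
]

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ActivityModel:
    """Signal model for one activity.

    gravity: unit orientation vector (projection of 1 g onto the sensor
    axes for the activity's posture).  osc_freq / osc_amp: per-axis
    frequency (Hz) and amplitude (g) of the dominant movement sinusoid.
    noise_sd: white accelerometer noise (g).  hr_target: steady-state heart
    rate (bpm) the activity drives toward; hr_tau: relaxation time (s).
    """

    name: str
    gravity: tuple[float, float, float]
    osc_freq: tuple[float, float, float]
    osc_amp: tuple[float, float, float]
    noise_sd: float
    hr_target: float
    hr_tau: float

    def __post_init__(self) -> None:
        if any(abs(g) > 1.0 + 1e-9 for g in self.gravity):
            raise ValueError("per-axis gravity projection cannot exceed 1 g")
        if any(a < 0 for a in self.osc_amp) or self.noise_sd < 0:
            raise ValueError("amplitudes and noise sd must be non-negative")
        if not (40 < self.hr_target < 220):
            raise ValueError(f"hr_target={self.hr_target} outside (40, 220)")
        if self.hr_tau <= 0:
            raise ValueError("hr_tau must be positive")


@dataclass(frozen=True)
class SessionScript:
    """An ordered activity schedule plus the subject parameters.

    The default protocol is eight 30-second blocks alternating exercise and
    rest: push-ups, resting, jogging, resting, squatting, resting, crunches,
    resting.
    """

    blocks: tuple[tuple[str, int], ...]
    age: int = 27
    hr_rest: float = 70.0

    def __post_init__(self) -> None:
        for activity, duration in self.blocks:
            if activity not in ACTIVITIES:
                raise ValueError(f"unknown activity {activity!r} in script")
            if duration <= 0:
                raise ValueError(f"block duration must be positive, got {duration}")

    @property
    def total_seconds(self) -> int:
        return sum(d for _, d in self.blocks)


def default_script(age: int = 27, hr_rest: float = 70.0) -> SessionScript:
    """The standard 8 x 30 s exercise/rest test routine (240 s)."""
    order = ["push-ups", "resting", "jogging", "resting",
             "squatting", "resting", "crunches", "resting"]
    return SessionScript(tuple((a, 30) for a in order), age=age, hr_rest=hr_rest)


def default_activity_models() -> dict[str, ActivityModel]:
    """Signal models for the five activities.

    Resting stands still upright (y axis vertical on the hip mount), pure
    gravity plus sensor noise.  Jogging keeps the upright posture with a
    fast (~2.5 Hz stride) large vertical oscillation; squatting a slow
    (~0.5 Hz) medium one.  Push-ups are prone (z axis vertical) and
    crunches supine (z axis inverted), each with sub-1 Hz oscillation.
    """
    models = [
        ActivityModel(
            name="resting",
            gravity=(0.0, 1.0, 0.0),
            osc_freq=(0.0, 0.0, 0.0),
            osc_amp=(0.0, 0.0, 0.0),
            noise_sd=0.03,
            hr_target=70.0,
            hr_tau=20.0,
        ),
        ActivityModel(
            name="jogging",
            gravity=(0.0, 1.0, 0.0),
            osc_freq=(2.5, 2.5, 2.5),
            osc_amp=(0.25, 0.80, 0.20),
            noise_sd=0.05,
            hr_target=150.0,
            hr_tau=20.0,
        ),
        ActivityModel(
            name="squatting",
            gravity=(0.0, 1.0, 0.0),
            osc_freq=(0.5, 0.5, 0.5),
            osc_amp=(0.05, 0.40, 0.10),
            noise_sd=0.04,
            hr_target=110.0,
            hr_tau=20.0,
        ),
        ActivityModel(
            name="push-ups",
            gravity=(0.0, 0.0, 1.0),
            osc_freq=(0.7, 0.7, 0.7),
            osc_amp=(0.08, 0.10, 0.35),
            noise_sd=0.04,
            hr_target=125.0,
            hr_tau=20.0,
        ),
        ActivityModel(
            name="crunches",
            gravity=(0.0, 0.0, -1.0),
            osc_freq=(0.6, 0.6, 0.6),
            osc_amp=(0.05, 0.12, 0.30),
            noise_sd=0.04,
            hr_target=115.0,
            hr_tau=20.0,
        ),
    ]
    return {m.name: m for m in models}


def generate_accel_stream(
    model: ActivityModel,
    duration_s: float,
    rate: int = SAMPLES_PER_SECOND,
    seed: int = 0,
) -> np.ndarray:
    """Raw accelerometer stream for one activity block.

    Returns an (duration × rate, 3) array in g.  Each axis is the gravity
    projection plus its sinusoid (phase randomized per seed, so windows are
    not phase-locked) plus Gaussian noise, clipped to the sensor full scale.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    signal = np.empty((n, 3))
    for k in range(3):
        signal[:, k] = (
            model.gravity[k]
            + model.osc_amp[k] * np.sin(2.0 * np.pi * model.osc_freq[k] * t + phases[k])
        )
    signal += rng.normal(0.0, model.noise_sd, size=(n, 3))
    return np.clip(signal, -ACCEL_FULL_SCALE_G, ACCEL_FULL_SCALE_G)


def generate_hr_stream(
    script: SessionScript,
    models: Mapping[str, ActivityModel],
    rate: int = 1,
    seed: int = 0,
    noise_sd: float = 1.5,
) -> np.ndarray:
    """1 Hz mean-HR series over a scripted session.

    First-order relaxation toward the current activity's target, one step
    per second, starting from the script's resting HR.
    """
    if rate != 1:
        raise ValueError("only the 1 Hz heart-rate record is modeled")
    rng = np.random.default_rng(seed)
    hr = float(script.hr_rest)
    out = []
    for activity, duration in script.blocks:
        model = models[activity]
        for _ in range(duration):
            hr = hr + (model.hr_target - hr) / model.hr_tau
            if noise_sd > 0:
                hr += rng.normal(0.0, noise_sd)
            hr = float(np.clip(hr, 30.0, 219.0))
            out.append(hr)
    return np.asarray(out)


def generate_session(
    script: Optional[SessionScript] = None,
    models: Optional[Mapping[str, ActivityModel]] = None,
    seed: int = 0,
    user_id: str = "synthetic-subject",
    start_timestamp_ms: int = 1_500_000_000_000,
    hr_noise_sd: float = 1.5,
) -> Session:
    """Full synthetic session: per-second records pairing 20 accelerometer
    samples with the 1 Hz HR value and the scripted activity label.

    Deterministic given (script, models, seed); timestamps advance in
    exactly 1000 ms steps.
    """
    if script is None:
        script = default_script()
    if models is None:
        models = default_activity_models()
    root = np.random.SeedSequence(seed)
    block_seeds = root.generate_state(len(script.blocks) + 1) % (2**31)
    hr_values = generate_hr_stream(
        script, models, seed=int(block_seeds[-1]), noise_sd=hr_noise_sd
    )

    records = []
    second = 0
    for b, (activity, duration) in enumerate(script.blocks):
        stream = generate_accel_stream(
            models[activity], duration, seed=int(block_seeds[b])
        )
        for s in range(duration):
            ts = start_timestamp_ms + second * 1000
            base_t = second * 1.0
            chunk = stream[s * SAMPLES_PER_SECOND : (s + 1) * SAMPLES_PER_SECOND]
            samples = tuple(
                AccelSample(
                    t=base_t + k * 0.050,
                    ax=float(chunk[k, 0]),
                    ay=float(chunk[k, 1]),
                    az=float(chunk[k, 2]),
                )
                for k in range(SAMPLES_PER_SECOND)
            )
            records.append(
                SecondRecord(
                    timestamp=ts,
                    user_id=user_id,
                    label=activity,
                    samples=samples,
                    mean_hr=float(hr_values[second]),
                )
            )
            second += 1
    return Session(
        user_id=user_id,
        records=tuple(records),
        age=script.age,
        hr_rest=script.hr_rest,
    )


def load_models_config(path: str | Path) -> dict[str, ActivityModel]:
    """Read activity models from a plain-text config file.

    One section per activity with ``key = value`` entries; vector-valued
    parameters are comma-separated triples, e.g.::

        [jogging]
        gravity = 0, 1, 0
        osc_freq = 2.5, 2.5, 2.5
        osc_amp = 0.25, 0.8, 0.2
        noise_sd = 0.05
        hr_target = 150
        hr_tau = 20

    Activities absent from the file keep their default model.
    """
    parser = configparser.ConfigParser()
    with open(path, "r", encoding="utf-8") as fh:
        parser.read_file(fh)
    models = dict(default_activity_models())
    for section in parser.sections():
        if section not in ACTIVITIES:
            raise ValueError(f"unknown activity section [{section}]")
        base = models[section]
        kwargs: dict = {}
        for key, raw in parser.items(section):
            if key in ("gravity", "osc_freq", "osc_amp"):
                parts = tuple(float(p) for p in raw.split(","))
                if len(parts) != 3:
                    raise ValueError(f"[{section}] {key} needs three comma-separated values")
                kwargs[key] = parts
            elif key in ("noise_sd", "hr_target", "hr_tau"):
                kwargs[key] = float(raw)
            else:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
        models[section] = replace(base, **kwargs)
    return models
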