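"""Data model and serialization for wearable sensor sessions.

A session is a sequence of per-second records, each carrying one second of
20 Hz triaxial accelerometry (20 samples, units of g) together with the mean
heart rate over that second (bpm) and an activity label.  Two on-disk
dialects are supported and interconvertible without loss:

* JSONL — one record object per line with keys ``timestamp`` (epoch ms),
  ``user_id``, ``label``, ``hr`` and the three 20-element axis arrays
  ``ax``, ``ay``, ``az``;
* CSV — long format, one accelerometer sample per row with columns
  ``timestamp_ms, user_id, label, hr, sample_idx, ax, ay, az``.

Session-level subject metadata (age, resting heart rate) is carried in an
optional leading metadata line (JSONL) or ``#`` comment line (CSV) so that a
write/read cycle is the identity on the whole session, not just its records.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ACTIVITIES",
    "SAMPLES_PER_SECOND",
    "AccelSample",
    "SecondRecord",
    "Session",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
]

#: Closed set of recognized activities, in canonical (alphabetical) order.
ACTIVITIES: tuple[str, ...] = (
    "crunches",
    "jogging",
    "push-ups",
    "resting",
    "squatting",
)

#: Accelerometer sampling rate is 20 Hz, so one second holds 20 samples.
SAMPLES_PER_SECOND: int = 20

#: Sensor full scale in units of g (ADXL335-class part, ±2 g).
ACCEL_FULL_SCALE_G: float = 2.0


class SessionValidationError(ValueError):
    """A record or session violates a structural invariant."""


class SessionFormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


@dataclass(frozen=True)
class AccelSample:
    """One timestamped triaxial accelerometer reading.

    Parameters
    ----------
    t : float
        Time in seconds from session start; non-negative.
    ax, ay, az : float
        Per-axis acceleration in units of g; |value| ≤ 2 (sensor full scale).
    """

    t: float
    ax: float
    ay: float
    az: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise SessionValidationError(f"sample time must be >= 0, got {self.t}")
        for axis in ("ax", "ay", "az"):
            v = getattr(self, axis)
            if not math.isfinite(v) or abs(v) > ACCEL_FULL_SCALE_G:
                raise SessionValidationError(
                    f"{axis}={v} outside sensor full scale ±{ACCEL_FULL_SCALE_G} g"
                )


@dataclass(frozen=True)
class SecondRecord:
    """One second of paired sensor data: 20 accelerometer samples + mean HR.

    ``mean_hr`` may be ``None`` for streams used for activity recognition
    alone; workload operations reject such records.
    """

    timestamp: int  # epoch milliseconds
    user_id: str
    label: str
    samples: tuple[AccelSample, ...]
    mean_hr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in ACTIVITIES:
            raise SessionValidationError(
                f"unknown activity label {self.label!r}; expected one of {ACTIVITIES}"
            )
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) != SAMPLES_PER_SECOND:
            raise SessionValidationError(
                f"record at timestamp {self.timestamp} has {len(samples)} samples, "
                f"expected exactly {SAMPLES_PER_SECOND}"
            )
        times = [s.t for s in samples]
        if any(b < a for a, b in zip(times, times[1:])):
            raise SessionValidationError(
                f"sample times within record at timestamp {self.timestamp} decrease"
            )
        if self.mean_hr is not None and not (20.0 < self.mean_hr < 250.0):
            raise SessionValidationError(
                f"mean_hr={self.mean_hr} outside plausible range (20, 250) bpm"
            )


@dataclass(frozen=True)
class Session:
    """An ordered stream of per-second records for one subject.

    ``age`` (years) and ``hr_rest`` (bpm) are the subject parameters needed
    for workload scoring; both are optional for recognition-only streams.
    """

    user_id: str
    records: tuple[SecondRecord, ...]
    age: Optional[int] = None
    hr_rest: Optional[float] = None

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        for rec in records:
            if rec.user_id != self.user_id:
                raise SessionValidationError(
                    f"record user_id {rec.user_id!r} != session user_id {self.user_id!r}"
                )
        stamps = [r.timestamp for r in records]
        if any(b <= a for a, b in zip(stamps, stamps[1:])):
            raise SessionValidationError("record timestamps must be strictly increasing")
        if self.age is not None and not (0 < self.age < 120):
            raise SessionValidationError(f"age={self.age} outside 1..119")
        if self.hr_rest is not None and self.hr_rest <= 0:
            raise SessionValidationError(f"hr_rest={self.hr_rest} must be positive")

    def __len__(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# serialization helpers

_META_KEY = "_meta"
_CSV_COLUMNS = ["timestamp_ms", "user_id", "label", "hr", "sample_idx", "ax", "ay", "az"]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _record_times(timestamp_ms: int, t0_ms: int) -> list[float]:
    # Intra-second times reconstructed from the 20 Hz rate: 50 ms spacing.
    base = (timestamp_ms - t0_ms) / 1000.0
    return [base + k * 0.050 for k in range(SAMPLES_PER_SECOND)]


def _build_record(
    timestamp_ms: int,
    user_id: str,
    label: str,
    hr: Optional[float],
    ax: Sequence[float],
    ay: Sequence[float],
    az: Sequence[float],
    t0_ms: int,
) -> SecondRecord:
    if not (len(ax) == len(ay) == len(az)):
        raise SessionValidationError(
            f"axis arrays of record at timestamp {timestamp_ms} differ in length"
        )
    times = _record_times(timestamp_ms, t0_ms)
    n = len(ax)
    if n != SAMPLES_PER_SECOND:
        raise SessionValidationError(
            f"record at timestamp {timestamp_ms} has {n} samples, "
            f"expected exactly {SAMPLES_PER_SECOND}"
        )
    samples = tuple(
        AccelSample(t=times[k], ax=float(ax[k]), ay=float(ay[k]), az=float(az[k]))
        for k in range(n)
    )
    return SecondRecord(
        timestamp=int(timestamp_ms),
        user_id=user_id,
        label=label,
        samples=samples,
        mean_hr=None if hr is None else float(hr),
    )


def read_session(path: str | Path, format: Optional[str] = None) -> Session:
    """Read a session from ``path`` in the JSONL or CSV dialect.

    Raises
    ------
    SessionFormatError
        Malformed content; the message names the offending line.
    SessionValidationError
        Structurally valid file whose records violate an invariant
        (wrong sample count, unknown label, non-increasing timestamps).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        return _read_jsonl(path)
    return _read_csv(path)


def _read_jsonl(path: Path) -> Session:
    meta: dict = {}
    raws: list[dict] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if not isinstance(obj, dict):
                raise SessionFormatError(f"{path}:{lineno}: expected a JSON object")
            if _META_KEY in obj:
                meta = obj[_META_KEY]
                continue
            missing = {"timestamp", "user_id", "label", "ax", "ay", "az"} - obj.keys()
            if missing:
                raise SessionFormatError(
                    f"{path}:{lineno}: record missing keys {sorted(missing)}"
                )
            obj["_lineno"] = lineno
            raws.append(obj)

    user_id = str(meta.get("user_id", raws[0]["user_id"] if raws else ""))
    records = []
    for obj in raws:
        try:
            records.append(
                _build_record(
                    timestamp_ms=int(obj["timestamp"]),
                    user_id=str(obj["user_id"]),
                    label=str(obj["label"]),
                    hr=obj.get("hr"),
                    ax=obj["ax"],
                    ay=obj["ay"],
                    az=obj["az"],
                    t0_ms=int(raws[0]["timestamp"]),
                )
            )
        except SessionValidationError as exc:
            raise SessionValidationError(f"{path}:{obj['_lineno']}: {exc}") from exc
    return Session(
        user_id=user_id,
        records=tuple(records),
        age=meta.get("age"),
        hr_rest=meta.get("hr_rest"),
    )


def _read_csv(path: Path) -> Session:
    import pandas as pd

    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("#").strip())
            except json.JSONDecodeError as exc:
                raise SessionFormatError(f"{path}:1: invalid metadata comment: {exc}") from exc

    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise SessionFormatError(f"{path}: CSV parse failure: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"{path}: CSV missing columns {sorted(missing)}")
    if df.empty:
        return Session(
            user_id=str(meta.get("user_id", "")),
            records=(),
            age=meta.get("age"),
            hr_rest=meta.get("hr_rest"),
        )

    t0_ms = int(df["timestamp_ms"].iloc[0])
    records = []
    for ts, group in df.groupby("timestamp_ms", sort=True):
        group = group.sort_values("sample_idx")
        hr = group["hr"].iloc[0]
        records.append(
            _build_record(
                timestamp_ms=int(ts),
                user_id=str(group["user_id"].iloc[0]),
                label=str(group["label"].iloc[0]),
                hr=None if pd.isna(hr) else float(hr),
                ax=group["ax"].to_numpy(),
                ay=group["ay"].to_numpy(),
                az=group["az"].to_numpy(),
                t0_ms=t0_ms,
            )
        )
    user_id = str(meta.get("user_id", records[0].user_id))
    return Session(
        user_id=user_id,
        records=tuple(records),
        age=meta.get("age"),
        hr_rest=meta.get("hr_rest"),
    )


def write_session(session: Session, path: str | Path, format: Optional[str] = None) -> None:
    """Write ``session`` to ``path``; floats keep ≥ 9 significant digits so
    that ``read_session(write_session(s)) == s`` for practical purposes."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        _write_jsonl(session, path)
    else:
        _write_csv(session, path)


def _meta_dict(session: Session) -> dict:
    meta: dict = {"user_id": session.user_id}
    if session.age is not None:
        meta["age"] = session.age
    if session.hr_rest is not None:
        meta["hr_rest"] = session.hr_rest
    return meta


def _write_jsonl(session: Session, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({_META_KEY: _meta_dict(session)}) + "\n")
        for rec in session.records:
            obj = {
                "timestamp": rec.timestamp,
                "user_id": rec.user_id,
                "label": rec.label,
                "hr": rec.mean_hr,
                "ax": [s.ax for s in rec.samples],
                "ay": [s.ay for s in rec.samples],
                "az": [s.az for s in rec.samples],
            }
            fh.write(json.dumps(obj) + "\n")


def _write_csv(session: Session, path: Path) -> None:
    import pandas as pd

    rows = []
    for rec in session.records:
        for k, s in enumerate(rec.samples):
            rows.append(
                (rec.timestamp, rec.user_id, rec.label, rec.mean_hr, k, s.ax, s.ay, s.az)
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(_meta_dict(session)) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def sessions_to_records(sessions: Iterable[Session]) -> list[SecondRecord]:
    """Flatten several sessions into one record list (corpus building)."""
    out: list[SecondRecord] = []
    for s in sessions:
        out.extend(s.records)
    return out
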