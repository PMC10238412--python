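"""Reading, writing and canonicalizing multi-rate tag sensor data.

Biologging tags record channels at heterogeneous rates (in the deployments
this package targets: pressure at 5-10 Hz, accelerometers up to 800 Hz,
magnetometers at 40 Hz).  This module defines the in-memory containers used
throughout the package and the plain-text interchange formats:

* a *sensor store* is a directory holding one CSV per rate group (all
  channels sharing a sampling rate), a ``channels.json`` sidecar with rates
  and units, and optionally a ``deployment.json`` with tag metadata;
* an *event table* is a single CSV with columns
  ``event_type,t_start,t_end,depth,attributes_json``.

Conventions (shared by every module):

* time is seconds since tag-on (sample ``k`` of a channel at rate ``fs``
  lies at ``k / fs``); the tag-on wall clock and its UTC offset live in
  :class:`Deployment`;
* depth is meters, positive down, 0 at the sea surface;
* acceleration is in g, magnetic field in microtesla.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SchemaError",
    "DataError",
    "CalibrationError",
    "ParameterError",
    "Deployment",
    "Channel",
    "SensorSeries",
    "EVENT_TYPES",
    "make_event_table",
    "validate_event_table",
    "read_sensor_table",
    "write_sensor_table",
    "downsample_series",
    "zero_depth_offset",
    "read_events",
    "write_events",
]


class SchemaError(ValueError):
    """A required channel/column is missing or misnamed."""


class DataError(ValueError):
    """Input data violates a structural precondition (e.g. non-monotone time)."""


class CalibrationError(RuntimeError):
    """A calibration step could not be performed (no surface found, too few points)."""


class ParameterError(ValueError):
    """An analysis parameter is infeasible for the data at hand."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

REQUIRED_CHANNELS = (
    "accel_x", "accel_y", "accel_z",
    "mag_x", "mag_y", "mag_z",
    "depth",
)

CANONICAL_UNITS = {
    "accel_x": "g", "accel_y": "g", "accel_z": "g",
    "mag_x": "uT", "mag_y": "uT", "mag_z": "uT",
    "depth": "m", "temp": "degC", "exhale_envelope": "au",
}


@dataclass(frozen=True)
class Deployment:
    """Metadata for one tag attachment."""

    whale_id: str
    tag_on: datetime
    tag_off: datetime
    latitude: float
    longitude: float
    body_length: float
    local_utc_offset: float

    def __post_init__(self) -> None:
        if self.tag_off <= self.tag_on:
            raise DataError("tag_off must be after tag_on")
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise DataError("latitude/longitude out of range")
        if not self.body_length > 0:
            raise DataError("body_length must be positive")

    @property
    def duration_s(self) -> float:
        return (self.tag_off - self.tag_on).total_seconds()

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    def local_hour_at(self, t: float | np.ndarray) -> np.ndarray:
        """Local clock hour-of-day at ``t`` seconds after tag-on."""
        h0 = self.tag_on.hour + self.tag_on.minute / 60 + self.tag_on.second / 3600
        return np.asarray((h0 + np.asarray(t, dtype=float) / 3600.0) % 24.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tag_on"] = self.tag_on.isoformat()
        d["tag_off"] = self.tag_off.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Deployment":
        d = dict(d)
        d["tag_on"] = datetime.fromisoformat(d["tag_on"])
        d["tag_off"] = datetime.fromisoformat(d["tag_off"])
        return cls(**d)


@dataclass
class Channel:
    """One uniformly sampled sensor channel."""

    data: np.ndarray
    rate: float
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not self.rate > 0:
            raise DataError("channel rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.rate

    @property
    def duration(self) -> float:
        return self.data.size / self.rate


@dataclass
class SensorSeries:
    """A named set of synchronized channels starting at tag-on (t = 0)."""

    channels: dict[str, Channel] = field(default_factory=dict)
    deployment: Deployment | None = None

    def __getitem__(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise SchemaError(f"missing channel {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def triplet(self, prefix: str) -> np.ndarray:
        """Stack ``prefix_x/y/z`` into an (n, 3) array (shared rate enforced)."""
        chans = [self[f"{prefix}_{ax}"] for ax in "xyz"]
        rates = {c.rate for c in chans}
        if len(rates) != 1:
            raise DataError(f"{prefix} triplet channels have differing rates")
        return np.column_stack([c.data for c in chans])

    def rate(self, prefix_or_name: str) -> float:
        name = prefix_or_name if prefix_or_name in self.channels else f"{prefix_or_name}_x"
        return self[name].rate


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

EVENT_TYPES = (
    "breath",
    "circle",
    "lunge",
    "glide_onset_descent",
    "glide_onset_ascent",
    "descent_end",
    "ascent_start",
)

EVENT_COLUMNS = ["event_type", "t_start", "t_end", "depth", "attributes"]


def make_event_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """Build a validated event table from row dicts (attributes is a dict)."""
    if not rows:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
        df["t_start"] = df["t_start"].astype(float)
        return df
    df = pd.DataFrame(rows)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("t_end", "depth") else None
    df["attributes"] = [a if isinstance(a, dict) else {} for a in df["attributes"]]
    df = df[EVENT_COLUMNS].sort_values("t_start", kind="stable").reset_index(drop=True)
    validate_event_table(df)
    return df


def validate_event_table(table: pd.DataFrame) -> None:
    bad = set(table["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise DataError(f"unknown event_type(s): {sorted(bad)}")
    t0 = table["t_start"].to_numpy(dtype=float)
    if len(t0) and (t0 < 0).any():
        raise DataError("t_start must be >= 0")
    if len(t0) and (np.diff(t0) < 0).any():
        raise DataError("event rows must be sorted by t_start")
    t1 = table["t_end"].to_numpy(dtype=float)
    ok = np.isnan(t1) | (t1 >= t0)
    if not ok.all():
        raise DataError("t_end must be >= t_start where present")


def write_events(path: str | os.PathLike, table: pd.DataFrame) -> None:
    """Write an event table as CSV (``attributes`` serialized to JSON)."""
    validate_event_table(table)
    out = table.copy()
    out["attributes_json"] = [json.dumps(a, sort_keys=True) for a in out["attributes"]]
    out = out[["event_type", "t_start", "t_end", "depth", "attributes_json"]]
    out.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"event_type", "t_start", "t_end", "depth", "attributes_json"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"event file missing column(s): {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        attrs = r["attributes_json"]
        rows.append({
            "event_type": r["event_type"],
            "t_start": float(r["t_start"]),
            "t_end": float(r["t_end"]) if np.isfinite(r["t_end"]) else np.nan,
            "depth": float(r["depth"]) if np.isfinite(r["depth"]) else np.nan,
            "attributes": json.loads(attrs) if isinstance(attrs, str) and attrs else {},
        })
    return make_event_table(rows)


# ---------------------------------------------------------------------------
# Sensor stores (directory of per-rate-group CSVs + JSON sidecar)
# ---------------------------------------------------------------------------

def write_sensor_table(path: str | os.PathLike, series: SensorSeries) -> None:
    """Write a SensorSeries to a directory store (one CSV per rate group)."""
    os.makedirs(path, exist_ok=True)
    groups: dict[float, list[str]] = {}
    for name, ch in series.channels.items():
        groups.setdefault(ch.rate, []).append(name)
    meta = {"channels": {}, "groups": {}}
    for i, (rate, names) in enumerate(sorted(groups.items())):
        fname = f"group_{i}.csv"
        cols = {"t": series.channels[names[0]].times}
        for n in sorted(names):
            cols[n] = series.channels[n].data
            meta["channels"][n] = {
                "rate": rate, "units": series.channels[n].units, "file": fname,
            }
        meta["groups"][fname] = {"rate": rate}
        pd.DataFrame(cols).to_csv(os.path.join(path, fname), index=False,
                                  float_format="%.17g")
    with open(os.path.join(path, "channels.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if series.deployment is not None:
        with open(os.path.join(path, "deployment.json"), "w") as fh:
            json.dump(series.deployment.to_dict(), fh, indent=1, sort_keys=True)


_UNIT_SCALE = {  # conversions into canonical units
    ("m/s^2", "g"): 1.0 / 9.81,
    ("mg", "g"): 1e-3,
    ("g", "g"): 1.0,
    ("nT", "uT"): 1e-3,
    ("uT", "uT"): 1.0,
    ("m", "m"): 1.0,
    ("cm", "m"): 1e-2,
}


def _canonicalize(name: str, data: np.ndarray, units: str) -> tuple[np.ndarray, str]:
    target = CANONICAL_UNITS.get(name)
    if target is None or not units or units == target:
        return data, units or (target or "")
    scale = _UNIT_SCALE.get((units, target))
    if scale is None:
        raise DataError(f"cannot convert channel {name!r} from {units!r} to {target!r}")
    return data * scale, target


def read_sensor_table(
    path: str | os.PathLike,
    schema: dict[str, str] | None = None,
) -> SensorSeries:
    """Read a sensor store directory into a :class:`SensorSeries`.

    ``schema`` optionally maps canonical channel names to the column names
    used in the files (e.g. ``{"accel_x": "Ax"}``).  Per-channel rates come
    from the sidecar when present, else are inferred from the ``t`` column.
    """
    path = os.fspath(path)
    meta = None
    meta_path = os.path.join(path, "channels.json")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    schema = schema or {}
    colmap = {v: k for k, v in schema.items()}  # file column -> canonical
    channels: dict[str, Channel] = {}
    files = sorted(f for f in os.listdir(path) if f.endswith(".csv"))
    if not files:
        raise SchemaError(f"no CSV files in sensor store {path!r}")
    for fname in files:
        df = pd.read_csv(os.path.join(path, fname))
        if "t" not in df.columns:
            raise SchemaError(f"{fname}: missing time column 't'")
        t = df["t"].to_numpy(dtype=float)
        if len(t) > 1 and (np.diff(t) <= 0).any():
            raise DataError(f"{fname}: non-monotone timestamps")
        if meta and fname in meta.get("groups", {}):
            rate = float(meta["groups"][fname]["rate"])
        elif len(t) > 1:
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            raise DataError(f"{fname}: cannot infer rate from a single sample")
        for col in df.columns:
            if col == "t":
                continue
            name = colmap.get(col, col)
            units = ""
            if meta and col in meta.get("channels", {}):
                units = meta["channels"][col].get("units", "")
            data, units = _canonicalize(name, df[col].to_numpy(dtype=float), units)
            channels[name] = Channel(data, rate, units or CANONICAL_UNITS.get(name, ""))
    missing = [c for c in REQUIRED_CHANNELS if c not in channels]
    if missing:
        raise SchemaError(f"missing required channel(s): {missing}")
    deployment = None
    dep_path = os.path.join(path, "deployment.json")
    if os.path.exists(dep_path):
        with open(dep_path) as fh:
            deployment = Deployment.from_dict(json.load(fh))
    return SensorSeries(channels, deployment)


# ---------------------------------------------------------------------------
# Canonicalization to the analysis rate
# ---------------------------------------------------------------------------

def _decimate(x: np.ndarray, q: int) -> np.ndarray:
    """Anti-aliased integer decimation, exact on constants.

    The channel mean is removed before filtering and restored afterwards so
    that a constant channel survives decimation bit-for-bit (FIR low-pass
    DC gain is only approximately unity).
    """
    if q == 1:
        return x.copy()
    mu = float(np.mean(x))
    y = signal.resample_poly(x - mu, up=1, down=q, padtype="line")
    return y + mu


def downsample_series(
    series: SensorSeries,
    target_rate: float,
    keep_native: tuple[str, ...] = ("accel_x", "accel_y", "accel_z"),
) -> SensorSeries:
    """Bring every channel to ``target_rate`` with anti-alias filtering.

    Channels already at the target rate are passed through untouched; the
    native-rate accelerometer triplet is retained under ``native_<name>``
    side channels so the tag-jiggle speed proxy can still see the
    high-frequency band.  Upsampling is refused.
    """
    out: dict[str, Channel] = {}
    for name, ch in series.channels.items():
        if ch.rate < target_rate - 1e-9:
            raise ParameterError(
                f"channel {name!r} at {ch.rate} Hz is below target "
                f"{target_rate} Hz; upsampling refused"
            )
        q = ch.rate / target_rate
        if abs(q - round(q)) > 1e-9:
            raise ParameterError(
                f"channel {name!r}: rate {ch.rate} is not an integer multiple "
                f"of target {target_rate}"
            )
        q = int(round(q))
        if name in keep_native and q > 1:
            out[f"native_{name}"] = Channel(ch.data.copy(), ch.rate, ch.units)
        out[name] = Channel(_decimate(ch.data, q), target_rate, ch.units)
    return SensorSeries(out, series.deployment)


def zero_depth_offset(
    depth: Channel,
    surface_window: float = 10.0,
    surface_tol: float = 1.5,
) -> Channel:
    """Remove a constant pressure offset using detected surface intervals.

    Samples within ``surface_tol`` meters of the record minimum that form
    runs of at least ``surface_window`` seconds are taken as surfacings; the
    median of those samples is mapped to 0 m.  Translation-covariant, hence
    idempotent.
    """
    x = depth.data
    near = x <= (np.min(x) + surface_tol)
    min_run = max(1, int(round(surface_window * depth.rate)))
    surf = _runs_of(near, min_run)
    if not surf.any():
        raise CalibrationError(
            f"no surface interval of >= {surface_window} s found"
        )
    return Channel(x - float(np.median(x[surf])), depth.rate, depth.units)


def _runs_of(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Boolean mask keeping only True-runs of at least ``min_len`` samples."""
    out = np.zeros_like(mask)
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def analysis_grid(series: SensorSeries, rate: float) -> np.ndarray:
    """Common time grid at the analysis rate covering all channels."""
    dur = min(ch.duration for ch in series.channels.values())
    n = int(math.floor(dur * rate + 1e-9))
    return np.arange(n) / rate
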