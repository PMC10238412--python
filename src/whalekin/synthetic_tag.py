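"""Synthetic tag-deployment generator with full ground truth.

Emulates the diel foraging regime of a deep-diving rorqual: daytime foraging
dives to a target depth with optional pre-lunge circling and 1-6 feeding
lunges per dive, night dominated by surface rest with occasional shallow
non-foraging dives, a post-dive surfacing bout with a configurable number of
breaths, and glide/fluke structure governed by a neutral-buoyancy depth
(fluking ceases at the configured glide-onset depth on descent and ascent).

The renderer produces piecewise-linear speed / pitch / roll / heading
profiles on a uniform truth grid; depth is the trapezoidal integral of
``-v sin(pitch)`` (positive down), which is exact whenever pitch is constant
and speed linear within a segment, so phase boundaries land exactly at the
configured depths.  True per-phase mechanical work is the exact integral of
the product of the linear interpolants of ``||a_sp||`` and ``v``, times body
mass.

``synthesize_sensors`` is the forward model inverted by
:mod:`whalekin.orientation_speed`: body-frame specific force from the true
orientation plus the propulsive acceleration, a speed-dependent band-limited
tag-jiggle component, tilt-rotated magnetometer triplets, pressure-derived
depth, and a one-pulse-per-breath exhalation envelope standing in for the
hydrophone record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .orientation_speed import GRAVITY, gravity_body_frame
from .tag_io import Channel, Deployment, ParameterError, SensorSeries, make_event_table

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Schedule",
    "DivePlan",
    "SurfacePlan",
    "GroundTruth",
    "build_schedule",
    "render_kinematics",
    "synthesize_sensors",
    "simulate_deployment",
    "make_deployment",
    "pairwise_linear_work",
    "demo_config",
]


class ConfigError(ParameterError):
    """The simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated deployment.

    Defaults follow the 2018-style tag regime (pressure 10 Hz, accelerometer
    800 Hz, magnetometer 40 Hz) and the observed behavioral envelope:
    foraging dives to 150-210 m by day, 1-6 lunges per dive with median 1,
    circling before roughly half to three quarters of lunges, lunge peak
    speeds near 5.6 m/s over a ~2 m/s cruise, ~30 deg lunge roll, and night
    spent predominantly within a few meters of the surface.
    """

    seed: int = 0
    duration_h: float = 24.0
    start_local_h: float = 9.0
    day_window: tuple[float, float] = (7.0, 19.0)     # local hours
    n_dives_per_hour_day: float = 4.0
    n_dives_per_hour_night: float = 2.0
    night_forage_frac: float = 0.1
    night_dive_depth: tuple[float, float] = (50.0, 100.0)
    dive_depth_mean: float = 180.0
    dive_depth_sd: float = 15.0
    lunges_per_dive_pmf: tuple[float, ...] = (0.55, 0.25, 0.10, 0.05, 0.03, 0.02)
    circle_before_lunge_prob: float = 0.6
    circle_duration_s: tuple[float, float] = (10.0, 60.0)
    circle_rotation_deg: tuple[float, float] = (200.0, 400.0)
    circle_jitter_sd_deg: float = 5.0
    lone_circle_prob: float = 0.15     # per-dive chance of a non-lunge circle
    lunge_peak_speed: float = 5.6
    cruise_speed: float = 2.0
    speed_jitter_sd: float = 0.25
    stroke_freq: float = 0.5
    fluke_amp: float = 0.5        # m/s^2, cruise stroke amplitude
    lunge_amp: float = 1.5        # m/s^2, stroke amplitude at lunge peak
    lunge_roll_deg: float = 30.0
    lunge_pitch_deg: float = 25.0
    pitch_descent_deg: float = -50.0
    pitch_ascent_deg: float = 50.0
    glide_onset_depth_descent: float = 26.0
    glide_onset_depth_ascent: float = 26.0
    breaths_per_surfacing: tuple[int, int] = (7, 13)  # inclusive uniform range
    breath_interval_s: float = 40.0                   # night resting spacing
    night_shallow_frac: float = 0.5                   # night surface time <= 2 m
    mass_kg: float = 6000.0
    # channel rates (Hz)
    truth_rate: float = 10.0
    accel_rate: float = 800.0
    mag_rate: float = 40.0
    depth_rate: float = 10.0
    envelope_rate: float = 10.0
    # sensor noise / nuisance parameters
    accel_noise_g: float = 0.003
    mag_noise_ut: float = 0.3
    depth_noise_m: float = 0.05
    depth_offset_m: float = 0.0
    jiggle_k_g: float = 0.006
    jiggle_c: float = 0.45
    jiggle_band_frac: tuple[float, float] = (0.25, 0.45)
    # slow multiplicative wander of the jiggle envelope (log-sd, corr. time):
    # tag jiggle is an imperfect flow-speed proxy, which is what keeps its
    # field calibrations against OCDR well below R^2 = 1
    jiggle_env_lognoise_sd: float = 0.15
    jiggle_env_corr_s: float = 20.0
    propulsion_axis: str = "x"    # "x" surge (realistic) | "z" heave
    mag_field_ut: tuple[float, float, float] = (25.0, 0.0, 40.0)
    # deployment metadata
    latitude: float = 28.757
    longitude: float = -85.705
    local_utc_offset: float = -5.0
    start_date: str = "2018-07-03"
    body_length_m: float = 9.2
    whale_id: str = "sim"

    def validate(self) -> None:
        if self.duration_h <= 0:
            raise ConfigError("duration must be positive")
        for name in ("truth_rate", "accel_rate", "mag_rate", "depth_rate",
                     "envelope_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.circle_before_lunge_prob <= 1:
            raise ConfigError("circle_before_lunge_prob must be in [0, 1]")
        if not 0 <= self.night_forage_frac <= 1:
            raise ConfigError("night_forage_frac must be in [0, 1]")
        if self.circle_duration_s[0] < 1:
            raise ConfigError("minimum circle duration must be >= 1 s")
        if self.lunge_peak_speed <= self.cruise_speed:
            raise ConfigError("lunge_peak_speed must exceed cruise_speed")
        if abs(sum(self.lunges_per_dive_pmf) - 1.0) > 1e-9:
            raise ConfigError("lunges_per_dive_pmf must sum to 1")
        if self.propulsion_axis not in ("x", "z"):
            raise ConfigError("propulsion_axis must be 'x' or 'z'")

    def noise_free(self) -> "SimulationConfig":
        """Copy with sensor noise, tag jiggle and depth offset switched off."""
        return replace(self, accel_noise_g=0.0, mag_noise_ut=0.0,
                       depth_noise_m=0.0, depth_offset_m=0.0, jiggle_k_g=0.0,
                       jiggle_env_lognoise_sd=0.0)


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A compact daytime deployment at desk-scale sensor rates.

    Roughly 20 foraging dives over three daylight hours with a 100 Hz
    accelerometer; used by the test-suite and the reproduction script so a
    multi-day 800 Hz deployment is never needed on a laptop.
    """
    base = dict(
        seed=seed,
        duration_h=3.0,
        start_local_h=8.0,
        n_dives_per_hour_day=8.0,
        dive_depth_mean=150.0,
        dive_depth_sd=10.0,
        accel_rate=100.0,
        mag_rate=20.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

@dataclass
class DivePlan:
    target_depth: float
    lunges: list          # per-lunge dicts: {"circle": None | circle dict}
    night: bool
    cycle_s: float        # dive + following surfacing budget
    n_breaths_after: int
    heading_deg: float
    v_descent: float
    v_ascent: float
    lone_circle: dict | None = None   # circling with no lunge (failed attempt)


@dataclass
class SurfacePlan:
    duration_s: float     # night rest block (day surfacings live in cycle_s)
    night: bool
    n_breaths: int


@dataclass
class Schedule:
    blocks: list
    config: SimulationConfig

    @property
    def dives(self) -> list:
        return [b for b in self.blocks if isinstance(b, DivePlan)]

    @property
    def n_dives(self) -> int:
        return len(self.dives)

    @property
    def n_lunges(self) -> int:
        return sum(len(d.lunges) for d in self.dives)


def _estimate_dive_duration(cfg: SimulationConfig, depth: float,
                            n_lunges: int) -> float:
    vert = cfg.cruise_speed * math.sin(math.radians(abs(cfg.pitch_descent_deg)))
    transit = 2.0 * depth / max(vert, 0.1)
    per_lunge = 45.0 + sum(cfg.circle_duration_s) / 2.0 * cfg.circle_before_lunge_prob
    return transit + 35.0 + n_lunges * per_lunge


def build_schedule(config: SimulationConfig) -> Schedule:
    """Lay out the behavioral timeline (deterministic given config.seed).

    Dive cycles nominally follow the configured per-hour rates; a dive whose
    own duration exceeds its nominal cycle stretches the cycle (whales do not
    truncate a dive to keep a schedule), but a configuration whose *minimal*
    one-lunge dive cannot fit the daytime cycle raises :class:`ConfigError`.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2 ** 31), 11]))
    day_cycle = 3600.0 / config.n_dives_per_hour_day
    if _estimate_dive_duration(config, config.dive_depth_mean, 1) + 30.0 > day_cycle:
        raise ConfigError(
            "a single-lunge dive to the mean depth does not fit the daytime "
            f"inter-dive cycle of {day_cycle:.0f} s; lower n_dives_per_hour_day "
            "or dive_depth_mean"
        )
    blocks: list = []
    t = 0.0
    total = config.duration_h * 3600.0
    lo, hi = config.day_window
    counts = np.arange(1, len(config.lunges_per_dive_pmf) + 1)
    while t < total - 60.0:
        local = (config.start_local_h + t / 3600.0) % 24.0
        is_day = lo <= local < hi
        if is_day:
            depth = float(np.clip(
                rng.normal(config.dive_depth_mean, config.dive_depth_sd), 20.0, None))
            n_lunges = int(rng.choice(counts, p=config.lunges_per_dive_pmf))
            nominal = day_cycle
        else:
            depth = float(rng.uniform(*config.night_dive_depth))
            n_lunges = (int(rng.choice(counts, p=config.lunges_per_dive_pmf))
                        if rng.random() < config.night_forage_frac else 0)
            nominal = 3600.0 / config.n_dives_per_hour_night
            # night is surface-dominated: rest for most of the cycle first
            est = _estimate_dive_duration(config, depth, n_lunges)
            rest = float(np.clip(nominal - est - 60.0, 120.0, total - t))
            blocks.append(SurfacePlan(
                duration_s=rest, night=True,
                n_breaths=max(1, int(rest / config.breath_interval_s))))
            t += rest
            nominal -= rest
            if t >= total - 60.0:
                break
        est = _estimate_dive_duration(config, depth, n_lunges)
        cycle = max(nominal, est + 45.0)
        lunges = []
        # alternate circle directions within a dive so that consecutive
        # rotations never merge into one long same-direction swing
        direction = float(rng.choice([-1.0, 1.0]))
        for _ in range(n_lunges):
            circle = None
            if rng.random() < config.circle_before_lunge_prob:
                circle = {
                    "duration": float(rng.uniform(*config.circle_duration_s)),
                    "rotation_deg": float(rng.uniform(*config.circle_rotation_deg)
                                          * direction),
                }
                direction = -direction
            lunges.append({"circle": circle})
        lone = None
        if rng.random() < config.lone_circle_prob:
            lone = {
                "duration": float(rng.uniform(*config.circle_duration_s)),
                "rotation_deg": float(rng.uniform(*config.circle_rotation_deg)
                                      * direction),
            }
        blocks.append(DivePlan(
            lone_circle=lone,
            target_depth=depth,
            lunges=lunges,
            night=not is_day,
            cycle_s=min(cycle, max(total - t, 90.0)),
            n_breaths_after=int(rng.integers(config.breaths_per_surfacing[0],
                                             config.breaths_per_surfacing[1] + 1)),
            heading_deg=float(rng.uniform(0.0, 360.0)),
            v_descent=float(np.clip(rng.normal(config.cruise_speed,
                                               config.speed_jitter_sd), 1.2, None)),
            v_ascent=float(np.clip(rng.normal(config.cruise_speed * 1.15,
                                              config.speed_jitter_sd), 1.2, None)),
        ))
        t += cycle
    return Schedule(blocks, config)


# ---------------------------------------------------------------------------
# Kinematic rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Truth-grid kinematics, true events and analytic per-phase work."""

    rate: float
    depth: np.ndarray
    speed: np.ndarray
    pitch: np.ndarray          # rad
    roll: np.ndarray           # rad
    heading: np.ndarray        # rad, continuous (unwrapped)
    a_sp_vec: np.ndarray       # (n, 3) body-frame specific acceleration, m/s^2
    events: pd.DataFrame
    phases: pd.DataFrame       # dive_id, phase, t_start, t_end, work_j
    config: SimulationConfig
    schedule: Schedule | None = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.depth.size) / self.rate

    @property
    def true_specific_accel(self) -> np.ndarray:
        return np.linalg.norm(self.a_sp_vec, axis=1)

    def dive_table(self) -> pd.DataFrame:
        """Per-dive truth: interval, max depth and lunge count."""
        ph = self.phases[self.phases["dive_id"] >= 0]
        rows = []
        for did, g in ph.groupby("dive_id"):
            t0, t1 = float(g["t_start"].min()), float(g["t_end"].max())
            sl = slice(int(round(t0 * self.rate)),
                       int(round(t1 * self.rate)) + 1)
            rows.append({
                "dive_id": int(did), "t_start": t0, "t_end": t1,
                "max_depth": float(self.depth[sl].max()),
                "n_lunges": int((g["phase"] == "lunge").sum()),
            })
        return pd.DataFrame(rows)


def _tri(phase: np.ndarray) -> np.ndarray:
    """Signed triangle wave, period 1, range [-1, 1], tri(0) = 1."""
    return 2.0 * np.abs(2.0 * np.mod(phase, 1.0) - 1.0) - 1.0


def pairwise_linear_work(a: np.ndarray, v: np.ndarray, dt: float,
                         mass: float) -> float:
    """Exact ``M * integral(a * v) dt`` for linear-interpolant a(t), v(t)."""
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    if a.size < 2:
        return 0.0
    a0, a1 = a[:-1], a[1:]
    v0, v1 = v[:-1], v[1:]
    seg = dt / 6.0 * (a0 * (2.0 * v0 + v1) + a1 * (v0 + 2.0 * v1))
    return float(mass * seg.sum())


class _Track:
    """Cursor-based renderer accumulating truth-grid segments.

    Depth is integrated incrementally with the same trapezoidal recurrence
    used for the final depth array, so segment durations solved in closed
    form land phase boundaries exactly at the configured depths.
    """

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.fs = cfg.truth_rate
        self.dt = 1.0 / self.fs
        self.rng = rng
        self.speed: list = []
        self.pitch: list = []
        self.roll: list = []
        self.heading: list = []
        self.amp: list = []            # stroke amplitude envelope, m/s^2
        self.marks: list = []          # phase interval marks (sample idx)
        self.events: list = []
        self.n = 0
        self.cur_v = 0.5
        self.cur_p = 0.0
        self.cur_r = 0.0
        self.cur_h = 0.0
        self.depth_now = 0.2
        self._last_f: float | None = None

    @property
    def t_now(self) -> float:
        return self.n * self.dt

    def emit(self, dur: float, *, v=None, p=None, r=None, dh: float = 0.0,
             amp=0.0, h_jitter: float = 0.0) -> int:
        """Append one segment of ``dur`` seconds.

        ``v``/``p``/``r`` may be scalars (linear ramp from the current value)
        or ``(start, end)`` pairs; ``amp`` a scalar (constant) or pair
        (ramp); ``dh`` is the total heading change over the segment.
        """
        m = max(1, int(round(dur * self.fs)))

        def ramp(spec, cur):
            if spec is None:
                return np.full(m, cur), cur
            if np.isscalar(spec):
                return np.linspace(cur, float(spec), m + 1)[1:], float(spec)
            a, b = spec
            return np.linspace(float(a), float(b), m + 1)[1:], float(b)

        v_arr, self.cur_v = ramp(v, self.cur_v)
        p_arr, self.cur_p = ramp(p, self.cur_p)
        r_arr, self.cur_r = ramp(r, self.cur_r)
        if np.isscalar(amp):
            amp_arr = np.full(m, float(amp))
        else:
            amp_arr = np.linspace(float(amp[0]), float(amp[1]), m + 1)[1:]
        h_arr = self.cur_h + np.linspace(dh / m, dh, m)
        if h_jitter > 0.0:
            h_arr = h_arr + self.rng.normal(0.0, h_jitter, m)
        self.cur_h = float(h_arr[-1])
        # incremental trapezoidal depth
        f_arr = -v_arr * np.sin(p_arr)
        prev = self._last_f if self._last_f is not None else f_arr[0]
        f_ext = np.concatenate([[prev], f_arr])
        self.depth_now += float(np.sum(self.dt * 0.5 * (f_ext[:-1] + f_ext[1:])))
        self._last_f = float(f_arr[-1])
        self.speed.append(v_arr)
        self.pitch.append(p_arr)
        self.roll.append(r_arr)
        self.heading.append(h_arr)
        self.amp.append(amp_arr)
        self.n += m
        return m

    def mark(self, dive_id: int, phase: str, i0: int, i1: int) -> None:
        if i1 >= i0:
            self.marks.append({"dive_id": dive_id, "phase": phase,
                               "i0": i0, "i1": i1})

    def event(self, etype: str, t: float, t_end=np.nan, depth=np.nan, **attrs):
        self.events.append({"event_type": etype, "t_start": float(t),
                            "t_end": t_end, "depth": depth,
                            "attributes": attrs})

    def arrays(self):
        return (np.concatenate(self.speed), np.concatenate(self.pitch),
                np.concatenate(self.roll), np.concatenate(self.heading),
                np.concatenate(self.amp))


def _depth_from(v: np.ndarray, pitch: np.ndarray, dt: float,
                d0: float = 0.2) -> np.ndarray:
    """Trapezoidal cumulative depth (positive down) of ``-v sin(pitch)``."""
    f = -v * np.sin(pitch)
    d = np.empty(v.size)
    d[0] = d0
    d[1:] = d0 + np.cumsum(dt * 0.5 * (f[:-1] + f[1:]))
    return d


def _vrate(v: float, pitch_deg: float) -> float:
    return v * math.sin(math.radians(abs(pitch_deg)))


def render_kinematics(schedule: Schedule) -> GroundTruth:
    """Render a schedule into truth-grid kinematics with analytic work."""
    cfg = schedule.config
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2 ** 31), 23]))
    tr = _Track(cfg, rng)
    tr.cur_h = math.radians(45.0)

    _surface_bout(tr, 30.0, n_breaths=1, night=False)
    dive_id = 0
    for block in schedule.blocks:
        if isinstance(block, SurfacePlan):
            _surface_bout(tr, block.duration_s, block.n_breaths,
                          night=block.night)
        else:
            t0 = tr.t_now
            _render_dive(tr, block, dive_id)
            surf = max(block.cycle_s - (tr.t_now - t0), 25.0)
            _surface_bout(tr, surf, block.n_breaths_after, night=block.night)
            dive_id += 1

    v, p, r, h, amp = tr.arrays()
    # signed propulsive stroke (triangle wave scaled by the amplitude
    # envelope) plus the net dv/dt; lateral centripetal term from yaw rate
    phase = cfg.stroke_freq * np.arange(v.size) * tr.dt
    stroke = amp * _tri(phase)
    dvdt = np.gradient(v) * tr.fs
    yaw_rate = np.gradient(h) * tr.fs
    a_vec = np.zeros((v.size, 3))
    # "x": realistic surge propulsion; "z": heave mode with the whole
    # propulsive signal on the gravity-aligned axis (estimator validation)
    axis = 0 if cfg.propulsion_axis == "x" else 2
    a_vec[:, axis] = stroke + dvdt
    a_vec[:, 1] = v * yaw_rate
    depth = _depth_from(v, p, tr.dt)

    events = make_event_table(tr.events)
    a_mag = np.linalg.norm(a_vec, axis=1)
    rows = []
    for mk in tr.marks:
        i0, i1 = mk["i0"], min(mk["i1"], v.size - 1)
        sl = slice(i0, i1 + 1)
        rows.append({
            "dive_id": mk["dive_id"], "phase": mk["phase"],
            "t_start": i0 * tr.dt, "t_end": i1 * tr.dt,
            "work_j": pairwise_linear_work(a_mag[sl], v[sl], tr.dt, cfg.mass_kg),
        })
    phases = pd.DataFrame(rows)
    return GroundTruth(rate=cfg.truth_rate, depth=depth, speed=v, pitch=p,
                       roll=r, heading=h, a_sp_vec=a_vec, events=events,
                       phases=phases, config=cfg, schedule=schedule)


# -- surface ---------------------------------------------------------------

_REST_DEPTH = 0.7       # m, surface rest band
_BREATH_RISE = 0.6      # m, depth excursion of one breath dip
_BREATH_PITCH = 45.0    # deg
_BREATH_SPEED = 0.5     # m/s


def _surface_bout(tr: _Track, dur: float, n_breaths: int, night: bool) -> None:
    i0 = tr.n
    cfg = tr.cfg
    if night and cfg.night_shallow_frac < 1.0 and dur > 180.0:
        n_cycles = max(1, int(dur / 240.0))
        # each excursion spends ~2 transit legs + ramp skirts above 2 m;
        # shift that time out of the rest budget so the realized occupancy
        # matches the configured night_shallow_frac
        trans = 2.0 * ((2.0 - _REST_DEPTH) / _vrate(1.0, 60.0) + 1.5)
        rest_c = max(dur * cfg.night_shallow_frac / n_cycles - trans, 20.0)
        sub_c = dur / n_cycles - rest_c
        nb = max(1, int(round(n_breaths / n_cycles)))
        for _ in range(n_cycles):
            _rest_with_breaths(tr, rest_c, nb)
            _subsurface_excursion(tr, sub_c)
    else:
        _rest_with_breaths(tr, dur, n_breaths)
    tr.mark(-1, "surface", i0, tr.n - 1)


def _ramp_msin(pitch_deg: float) -> float:
    """Time-mean |sin(pitch)| of a linear ramp between 0 and ``pitch_deg``."""
    a = math.radians(abs(pitch_deg))
    return (1.0 - math.cos(a)) / a if a > 0 else 0.0


def _pitch_excursion(tr: _Track, rise_m: float, pitch_deg: float, v: float,
                     amp: float = 0.0) -> float:
    """Symmetric up-then-down (or down-then-up) depth excursion.

    Four equal quarter-segments ramp pitch 0 -> +/-P -> 0 -> -/+P -> 0; the
    time-averaged sine of mirrored ramps cancels exactly, so the net depth
    change is zero.  ``rise_m`` > 0 moves toward the surface first.
    Returns the total time spent.
    """
    sgn = 1.0 if rise_m >= 0 else -1.0
    q = abs(rise_m) / (2.0 * v * _ramp_msin(pitch_deg))
    p = math.radians(pitch_deg)
    tr.emit(q, v=v, p=sgn * p)
    tr.emit(q, v=v, p=0.0)
    tr.emit(q, v=v, p=-sgn * p)
    tr.emit(q, v=v, p=0.0)
    return 4.0 * q


def _settle_to(tr: _Track, target_depth: float, v: float = 0.6,
               pitch_deg: float = 40.0, amp: float = 0.0) -> float:
    """Steer depth to ``target_depth`` with a ramp-hold-ramp pitch profile."""
    delta = target_depth - tr.depth_now
    if abs(delta) < 0.05:
        return 0.0
    sgn = -1.0 if delta > 0 else 1.0        # pitch down to go deeper
    msin = _ramp_msin(pitch_deg)
    full = _vrate(v, pitch_deg)
    tb = 1.0
    hold = (abs(delta) - 2.0 * tb * v * msin) / full
    if hold < 0:
        tb = abs(delta) / (2.0 * v * msin)
        hold = 0.0
    t0 = tr.t_now
    p = math.radians(pitch_deg)
    tr.emit(tb, v=v, p=sgn * p, amp=amp)
    if hold > tr.dt:
        tr.emit(hold, v=v, p=sgn * p, amp=amp)
    tr.emit(tb, v=v, p=0.0, amp=amp)
    return tr.t_now - t0


def _rest_with_breaths(tr: _Track, dur: float, n_breaths: int) -> None:
    """Surface rest near 0.7 m with symmetric breath dips to ~0.1 m."""
    t_end = tr.t_now + dur
    _settle_to(tr, _REST_DEPTH)
    breath_t = 2.0 * _BREATH_RISE / (_BREATH_SPEED * _ramp_msin(_BREATH_PITCH))
    n_fit = max(0, int((t_end - tr.t_now - 2.0) / (breath_t + 3.0)))
    n_breaths = min(int(n_breaths), n_fit)
    if n_breaths == 0:
        if t_end - tr.t_now > tr.dt:
            _hold_band(tr, t_end - tr.t_now)
        return
    spacing = (t_end - tr.t_now) / n_breaths
    for _ in range(n_breaths):
        lead = spacing - breath_t
        if lead > tr.dt:
            _hold_band(tr, lead)
        tr.event("breath", tr.t_now + breath_t / 2.0,
                 depth=max(tr.depth_now - _BREATH_RISE, 0.05))
        _pitch_excursion(tr, _BREATH_RISE, _BREATH_PITCH, _BREATH_SPEED)
    if t_end - tr.t_now > tr.dt:
        _hold_band(tr, t_end - tr.t_now)


def _hold_band(tr: _Track, dur: float, v: float = 0.5) -> None:
    """Hold depth with tiny symmetric pitch wobbles (exact zero net)."""
    n_sub = max(1, int(round(dur / 4.0)))
    sub = dur / n_sub
    amp_rise = v * _ramp_msin(3.0) * sub / 2.0
    for j in range(n_sub):
        sign = 1.0 if j % 2 == 0 else -1.0
        _pitch_excursion(tr, sign * amp_rise, 3.0, v)


def _subsurface_excursion(tr: _Track, dur: float) -> None:
    """Shallow (4-6 m) sub-surface block used during night rest."""
    target = float(tr.rng.uniform(4.0, 6.0))
    t_end = tr.t_now + dur
    _settle_to(tr, target, v=1.0, pitch_deg=60.0)
    t_back = (target - _REST_DEPTH) / _vrate(1.0, 60.0) + 2.0
    hold = t_end - tr.t_now - t_back
    if hold > 1.0:
        _hold_band(tr, hold, v=0.8)
    _settle_to(tr, _REST_DEPTH, v=1.0, pitch_deg=60.0)


# -- dives -----------------------------------------------------------------

def _render_dive(tr: _Track, plan: DivePlan, dive_id: int) -> None:
    cfg = tr.cfg
    dt = tr.dt
    pd_rad = math.radians(cfg.pitch_descent_deg)
    pa_rad = math.radians(cfg.pitch_ascent_deg)
    g_desc = min(cfg.glide_onset_depth_descent, plan.target_depth * 0.6)
    g_asc = min(cfg.glide_onset_depth_ascent, plan.target_depth * 0.6)
    # gradual sub-180 deg course change on the descent, turned against the
    # first circle's direction so it can never merge with a circling swing
    first_circle = next((lg["circle"] for lg in plan.lunges
                         if lg["circle"] is not None), plan.lone_circle)
    turn_sign = (-math.copysign(1.0, first_circle["rotation_deg"])
                 if first_circle else float(tr.rng.choice([-1.0, 1.0])))
    dh_turn = turn_sign * math.radians(float(tr.rng.uniform(30.0, 150.0)))

    # --- descent: fluke to the glide-onset depth, then glide to target
    i0 = tr.n
    tr.emit(3.0, v=plan.v_descent, p=pd_rad, r=0.0, amp=cfg.fluke_amp)
    rate = _vrate(plan.v_descent, cfg.pitch_descent_deg)
    tr.emit(max((g_desc - tr.depth_now) / rate, dt), v=plan.v_descent,
            p=pd_rad, amp=cfg.fluke_amp, dh=dh_turn)
    tr.event("glide_onset_descent", tr.t_now, depth=tr.depth_now,
             dive_id=dive_id)
    v_g = (plan.v_descent, plan.v_descent * 0.8)
    rate_g = _vrate(sum(v_g) / 2.0, cfg.pitch_descent_deg)
    # stop the glide short by the depth gained while leveling off (2 s ramp)
    level_gain = cfg.cruise_speed * 2.0 * _ramp_msin(cfg.pitch_descent_deg)
    tr.emit(max((plan.target_depth - level_gain - tr.depth_now) / rate_g, dt),
            v=v_g, p=pd_rad, amp=0.0)
    tr.emit(2.0, v=cfg.cruise_speed, p=0.0, amp=cfg.fluke_amp)
    tr.mark(dive_id, "descent", i0, tr.n - 1)
    tr.event("descent_end", tr.t_now, depth=tr.depth_now, dive_id=dive_id)
    bottom_depth = tr.depth_now

    # --- bottom: swim / circle / lunge / regain
    for lg in plan.lunges:
        ib = tr.n
        tr.emit(float(tr.rng.uniform(10.0, 25.0)), v=cfg.cruise_speed, p=0.0,
                r=0.0, amp=cfg.fluke_amp)
        tr.mark(dive_id, "bottom", ib, tr.n - 1)
        if lg["circle"] is not None:
            ic = tr.n
            c = lg["circle"]
            t_c0 = tr.t_now
            tr.emit(c["duration"], v=(cfg.cruise_speed, cfg.cruise_speed * 1.2),
                    p=0.0, dh=math.radians(c["rotation_deg"]),
                    h_jitter=math.radians(cfg.circle_jitter_sd_deg)
                    / math.sqrt(tr.fs), amp=cfg.fluke_amp)
            tr.event("circle", t_c0, t_end=tr.t_now, depth=tr.depth_now,
                     dive_id=dive_id, rotation_deg=c["rotation_deg"],
                     followed_by_lunge=True)
            tr.mark(dive_id, "circle", ic, tr.n - 1)
        _render_lunge(tr, dive_id, bottom_depth)
    if plan.lone_circle is not None:
        ib = tr.n
        tr.emit(float(tr.rng.uniform(8.0, 15.0)), v=cfg.cruise_speed, p=0.0,
                r=0.0, amp=cfg.fluke_amp)
        tr.mark(dive_id, "bottom", ib, tr.n - 1)
        ic = tr.n
        c = plan.lone_circle
        t_c0 = tr.t_now
        tr.emit(c["duration"], v=cfg.cruise_speed, p=0.0,
                dh=math.radians(c["rotation_deg"]),
                h_jitter=math.radians(cfg.circle_jitter_sd_deg)
                / math.sqrt(tr.fs), amp=cfg.fluke_amp)
        tr.event("circle", t_c0, t_end=tr.t_now, depth=tr.depth_now,
                 dive_id=dive_id, rotation_deg=c["rotation_deg"],
                 followed_by_lunge=False)
        tr.mark(dive_id, "circle", ic, tr.n - 1)
    ib = tr.n
    tr.emit(float(tr.rng.uniform(10.0, 20.0)), v=cfg.cruise_speed, p=0.0,
            r=0.0, amp=cfg.fluke_amp)
    tr.mark(dive_id, "bottom", ib, tr.n - 1)

    # --- ascent: fluke to the glide-onset depth, then glide to the surface
    ia = tr.n
    tr.event("ascent_start", tr.t_now, depth=tr.depth_now, dive_id=dive_id)
    tr.emit(3.0, v=plan.v_ascent, p=pa_rad, r=0.0, amp=cfg.fluke_amp)
    rate = _vrate(plan.v_ascent, cfg.pitch_ascent_deg)
    tr.emit(max((tr.depth_now - g_asc) / rate, dt), v=plan.v_ascent, p=pa_rad,
            amp=cfg.fluke_amp)
    tr.event("glide_onset_ascent", tr.t_now, depth=tr.depth_now,
             dive_id=dive_id)
    v_g = (plan.v_ascent, plan.v_ascent * 0.9)
    rate_g = _vrate(sum(v_g) / 2.0, cfg.pitch_ascent_deg)
    # stop the glide deep enough that the 1 s leveling ramp ends near 0.4 m
    level_rise = (v_g[1] + 0.5) / 2.0 * _ramp_msin(cfg.pitch_ascent_deg)
    tr.emit(max((tr.depth_now - 0.4 - level_rise) / rate_g, dt),
            v=v_g, p=pa_rad, amp=0.0)
    tr.emit(1.0, v=0.5, p=0.0)
    tr.mark(dive_id, "ascent", ia, tr.n - 1)


def _render_lunge(tr: _Track, dive_id: int, bottom_depth: float) -> None:
    cfg = tr.cfg
    lp = math.radians(cfg.lunge_pitch_deg)
    lr = math.radians(cfg.lunge_roll_deg) * float(tr.rng.choice([-1.0, 1.0]))
    il = tr.n
    v_mid = cfg.cruise_speed + 0.6 * (cfg.lunge_peak_speed - cfg.cruise_speed)
    # acceleration: pitch up, speed toward peak, roll begins just before it
    tr.emit(5.0, v=v_mid, p=lp, r=0.0, amp=(cfg.fluke_amp, cfg.lunge_amp))
    tr.emit(3.0, v=cfg.lunge_peak_speed, p=lp, r=lr, amp=cfg.lunge_amp)
    tr.event("lunge", tr.t_now, depth=tr.depth_now, dive_id=dive_id,
             peak_speed=cfg.lunge_peak_speed)
    # deceleration below pre-lunge speed; pitch rises then angles down
    tr.emit(3.0, v=cfg.cruise_speed,
            p=math.radians(cfg.lunge_pitch_deg + 5.0), r=lr, amp=cfg.lunge_amp)
    tr.emit(3.0, v=cfg.cruise_speed * 0.7, p=math.radians(-20.0), r=0.0,
            amp=(cfg.lunge_amp, cfg.fluke_amp))
    tr.emit(4.0, v=cfg.cruise_speed, p=0.0, amp=cfg.fluke_amp)
    tr.mark(dive_id, "lunge", il, tr.n - 1)
    # regain the bottom depth lost during the upward lunge
    if abs(bottom_depth - tr.depth_now) > 1.0:
        ir = tr.n
        _settle_to(tr, bottom_depth, v=cfg.cruise_speed, pitch_deg=25.0,
                   amp=cfg.fluke_amp)
        tr.emit(2.0, v=cfg.cruise_speed, p=0.0, amp=cfg.fluke_amp)
        tr.mark(dive_id, "bottom", ir, tr.n - 1)


# ---------------------------------------------------------------------------
# Sensor synthesis
# ---------------------------------------------------------------------------

def synthesize_sensors(truth: GroundTruth,
                       config: SimulationConfig | None = None) -> SensorSeries:
    """Render truth kinematics into multi-rate sensor channels."""
    cfg = config or truth.config
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % (2 ** 31), 37]))
    t_truth = truth.t
    dur = float(t_truth[-1])

    def grid(rate):
        return np.arange(int(math.floor(dur * rate)) + 1) / rate

    # --- accelerometer at native rate
    ta = grid(cfg.accel_rate)
    pitch_a = np.interp(ta, t_truth, truth.pitch)
    roll_a = np.interp(ta, t_truth, truth.roll)
    acc = gravity_body_frame(pitch_a, roll_a)
    for k in range(3):
        acc[:, k] += np.interp(ta, t_truth, truth.a_sp_vec[:, k]) / GRAVITY
    if cfg.jiggle_k_g > 0:
        v_a = np.interp(ta, t_truth, truth.speed)
        lo = cfg.jiggle_band_frac[0] * cfg.accel_rate
        hi = cfg.jiggle_band_frac[1] * cfg.accel_rate
        sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=cfg.accel_rate,
                          output="sos")
        env = cfg.jiggle_k_g * np.exp(cfg.jiggle_c * v_a)
        if cfg.jiggle_env_lognoise_sd > 0:
            # slow multiplicative wander: the vibration/speed coupling drifts
            # with tag placement and flow angle, as it does on real tags
            n_nodes = max(int(dur / cfg.jiggle_env_corr_s) + 2, 2)
            t_nodes = np.linspace(0.0, dur, n_nodes)
            g = rng.normal(0.0, cfg.jiggle_env_lognoise_sd, n_nodes)
            env = env * np.exp(np.interp(ta, t_nodes, g))
        for k in range(3):
            w = _sig.sosfiltfilt(sos, rng.standard_normal(ta.size))
            w /= max(float(np.sqrt(np.mean(w ** 2))), 1e-12)
            acc[:, k] += env / math.sqrt(3.0) * w
    if cfg.accel_noise_g > 0:
        acc += rng.normal(0.0, cfg.accel_noise_g, acc.shape)

    # --- magnetometer: body-frame rotation of the fixed field vector
    tm = grid(cfg.mag_rate)
    pm = np.interp(tm, t_truth, truth.pitch)
    rm = np.interp(tm, t_truth, truth.roll)
    hm = np.interp(tm, t_truth, truth.heading)
    bx, by, bz = cfg.mag_field_ut
    ch, sh = np.cos(hm), np.sin(hm)
    b1x = ch * bx + sh * by
    b1y = -sh * bx + ch * by
    cp, sp = np.cos(pm), np.sin(pm)
    b2x = cp * b1x - sp * bz
    b2z = sp * b1x + cp * bz
    cr, sr = np.cos(rm), np.sin(rm)
    mag = np.column_stack([b2x, cr * b1y + sr * b2z, -sr * b1y + cr * b2z])
    if cfg.mag_noise_ut > 0:
        mag += rng.normal(0.0, cfg.mag_noise_ut, mag.shape)

    # --- depth
    td = grid(cfg.depth_rate)
    depth = np.interp(td, t_truth, truth.depth) + cfg.depth_offset_m
    if cfg.depth_noise_m > 0:
        depth += rng.normal(0.0, cfg.depth_noise_m, depth.shape)

    # --- exhalation envelope: one pulse per breath
    te = grid(cfg.envelope_rate)
    env_ch = np.zeros(te.size)
    for t_b in truth.events.loc[truth.events["event_type"] == "breath",
                                "t_start"].to_numpy(dtype=float):
        j0 = np.searchsorted(te, t_b - 1.5)
        j1 = np.searchsorted(te, t_b + 1.5)
        env_ch[j0:j1] += np.exp(-0.5 * ((te[j0:j1] - t_b) / 0.2) ** 2)
    env_ch += np.abs(rng.normal(0.0, 0.01, te.size))

    channels = {
        "accel_x": Channel(acc[:, 0], cfg.accel_rate, "g"),
        "accel_y": Channel(acc[:, 1], cfg.accel_rate, "g"),
        "accel_z": Channel(acc[:, 2], cfg.accel_rate, "g"),
        "mag_x": Channel(mag[:, 0], cfg.mag_rate, "uT"),
        "mag_y": Channel(mag[:, 1], cfg.mag_rate, "uT"),
        "mag_z": Channel(mag[:, 2], cfg.mag_rate, "uT"),
        "depth": Channel(depth, cfg.depth_rate, "m"),
        "exhale_envelope": Channel(env_ch, cfg.envelope_rate, "au"),
    }
    return SensorSeries(channels, make_deployment(cfg, dur))


def make_deployment(cfg: SimulationConfig,
                    duration_s: float | None = None) -> Deployment:
    y, m, d = (int(x) for x in cfg.start_date.split("-"))
    tz = timezone(timedelta(hours=cfg.local_utc_offset))
    h = int(cfg.start_local_h)
    mn = int(round((cfg.start_local_h - h) * 60)) % 60
    tag_on = datetime(y, m, d, h, mn, tzinfo=tz)
    dur = duration_s if duration_s is not None else cfg.duration_h * 3600.0
    return Deployment(
        whale_id=cfg.whale_id, tag_on=tag_on,
        tag_off=tag_on + timedelta(seconds=float(dur)),
        latitude=cfg.latitude, longitude=cfg.longitude,
        body_length=cfg.body_length_m, local_utc_offset=cfg.local_utc_offset,
    )


def simulate_deployment(config: SimulationConfig,
                        ) -> tuple[SensorSeries, GroundTruth]:
    """Schedule -> kinematic truth -> sensors, deterministic from the seed."""
    schedule = build_schedule(config)
    truth = render_kinematics(schedule)
    sensors = synthesize_sensors(truth, config)
    return sensors, truth
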