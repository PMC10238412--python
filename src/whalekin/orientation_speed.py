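"""Orientation, swim-speed and minimum-specific-acceleration estimation.

Body frame is NED-style: x forward (rostral), y right, z down.  At rest and
level, the accelerometer reads the specific force ``(0, 0, -1)`` g.  Pitch is
positive nose-up, roll positive right-side-down, heading clockwise from
magnetic north in ``[0, 2*pi)``.

Speed comes from two complementary estimators:

* **OCDR** (orientation-corrected depth rate): vertical depth rate divided by
  ``|sin(pitch)|``, valid only on steep descent/ascent segments where the
  1/sin amplification is bounded;
* **tag jiggle**: the RMS of the high-frequency tag vibration band grows
  with flow speed; a log-linear regression of OCDR on ln(jiggle RMS)
  calibrates jiggle into a continuous speed series.

The minimum specific acceleration (MSA), ``| ||accel|| - 1 g |``, is a
per-sample lower bound on the magnitude of the propulsive (specific)
acceleration; it supplies the ``a`` of the power product ``P = M a v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .tag_io import ParameterError, CalibrationError

__all__ = [
    "GRAVITY",
    "OrientationSeries",
    "SpeedSeries",
    "MsaSeries",
    "euler_to_matrix",
    "split_static_dynamic",
    "compute_pitch_roll",
    "compute_heading",
    "compute_ocdr_speed",
    "compute_jiggle",
    "JiggleUnavailable",
    "calibrate_jiggle_speed",
    "compute_msa",
]

GRAVITY = 9.81  # m/s^2


@dataclass
class OrientationSeries:
    pitch: np.ndarray      # rad, +nose-up; NaN where masked
    roll: np.ndarray       # rad, +right-side-down
    heading: np.ndarray    # rad clockwise from north, [0, 2*pi)
    static_accel: np.ndarray   # (n, 3) g
    dynamic_accel: np.ndarray  # (n, 3) g
    rate: float


@dataclass
class SpeedSeries:
    speed: np.ndarray          # m/s, NaN where invalid
    rate: float
    source: str                # "jiggle" | "ocdr" | "blend"
    calibration: dict = field(default_factory=dict)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.speed)


@dataclass
class MsaSeries:
    msa: np.ndarray  # m/s^2, >= 0
    rate: float


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

def euler_to_matrix(heading: float, pitch: float, roll: float) -> np.ndarray:
    """Body-to-world rotation R = Rz(heading) @ Ry(pitch) @ Rx(roll) (NED)."""
    ch, sh = np.cos(heading), np.sin(heading)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    rz = np.array([[ch, -sh, 0.0], [sh, ch, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cr, -sr], [0.0, sr, cr]])
    return rz @ ry @ rx


def gravity_body_frame(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """Specific force (g units) read by a motionless accelerometer at (pitch, roll)."""
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    return np.stack(
        [np.sin(pitch), -np.cos(pitch) * np.sin(roll), -np.cos(pitch) * np.cos(roll)],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# Static/dynamic split
# ---------------------------------------------------------------------------

def split_static_dynamic(
    accel: np.ndarray, rate: float, cutoff: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase low-pass split of the accelerometer triplet.

    ``static`` is the gravity estimate (low-pass at ``cutoff``), ``dynamic``
    the residual; ``static + dynamic == accel`` exactly by construction.
    """
    accel = np.asarray(accel, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ParameterError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate/2})")
    sos = signal.butter(3, cutoff, btype="low", fs=rate, output="sos")
    mu = accel.mean(axis=0, keepdims=True)
    static = signal.sosfiltfilt(sos, accel - mu, axis=0) + mu
    return static, accel - static


# ---------------------------------------------------------------------------
# Pitch / roll / heading
# ---------------------------------------------------------------------------

def compute_pitch_roll(static_accel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pitch and roll from the static specific force.

    ``pitch = asin(f_x / ||f||)``; ``roll = atan2(-f_y, -f_z)``.  Frames with
    zero norm (or norm outside [0.5, 1.5] g, i.e. dominated by non-gravity
    acceleration) are masked with NaN.
    """
    f = np.asarray(static_accel, dtype=float)
    norm = np.linalg.norm(f, axis=-1)
    bad = (norm < 0.5) | (norm > 1.5)
    with np.errstate(invalid="ignore", divide="ignore"):
        pitch = np.arcsin(np.clip(f[..., 0] / np.where(norm > 0, norm, np.nan), -1, 1))
    roll = np.arctan2(-f[..., 1], -f[..., 2])
    pitch = np.where(bad, np.nan, pitch)
    roll = np.where(bad, np.nan, roll)
    return pitch, roll


def compute_heading(
    pitch: np.ndarray,
    roll: np.ndarray,
    mag: np.ndarray,
    declination: float = 0.0,
    min_horizontal: float = 1e-3,
) -> np.ndarray:
    """Tilt-compensated heading, clockwise from north, wrapped to [0, 2*pi).

    The magnetometer triplet is de-rotated by roll then pitch into the
    horizontal plane; heading is the atan2 of the horizontal components plus
    the local declination (degrees).  Samples whose horizontal field
    magnitude falls below ``min_horizontal`` (relative to the total field)
    are masked: there the field is near-vertical and heading is undefined.
    """
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    m = np.asarray(mag, dtype=float)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    # Ry(pitch) @ Rx(roll) @ m  (body -> de-tilted frame)
    mx, my, mz = m[..., 0], m[..., 1], m[..., 2]
    x1 = mx
    y1 = cr * my - sr * mz
    z1 = sr * my + cr * mz
    xh = cp * x1 + sp * z1
    yh = y1
    horiz = np.hypot(xh, yh)
    total = np.linalg.norm(m, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = horiz / np.where(total > 0, total, np.nan)
    heading = np.arctan2(-yh, xh) + np.deg2rad(declination)
    heading = np.mod(heading, 2 * np.pi)
    heading = np.where(np.isnan(frac) | (frac < min_horizontal), np.nan, heading)
    return np.where(np.isnan(pitch), np.nan, heading)


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------

def compute_ocdr_speed(
    depth: np.ndarray,
    pitch: np.ndarray,
    rate: float,
    min_abs_pitch: float = np.deg2rad(30.0),
    smooth_s: float = 1.0,
) -> SpeedSeries:
    """Orientation-corrected depth rate: ``|d(depth)/dt| / |sin(pitch)|``.

    Valid only where ``|pitch| >= min_abs_pitch`` (default 30 deg), which
    bounds the 1/sin error amplification; other samples are NaN.  The depth
    rate is smoothed over ``smooth_s`` seconds to tame sensor noise.
    """
    depth = np.asarray(depth, dtype=float)
    dzdt = np.gradient(depth) * rate
    w = max(1, int(round(smooth_s * rate)))
    if w > 1:
        kernel = np.ones(w) / w
        dzdt = np.convolve(dzdt, kernel, mode="same")
    sp = np.abs(np.sin(np.asarray(pitch, dtype=float)))
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.abs(dzdt) / sp
    speed = np.where(np.abs(pitch) >= min_abs_pitch, speed, np.nan)
    return SpeedSeries(speed, rate, source="ocdr")


class JiggleUnavailable(ParameterError):
    """The jiggle band is infeasible at the native accelerometer rate."""


def compute_jiggle(
    native_accel: np.ndarray,
    native_rate: float,
    band: tuple[float, float] = (10.0, 45.0),
    window: float = 1.0,
    out_rate: float | None = None,
) -> tuple[np.ndarray, float]:
    """Windowed RMS of the band-passed tag-vibration signal.

    Each accelerometer axis is band-passed to ``band`` (Hz), the per-sample
    vector magnitude squared is averaged over a centered sliding ``window``
    (s), and the square root is resampled onto the analysis rate
    ``out_rate``.  Returns ``(jiggle_rms, out_rate)`` in g.

    Raises :class:`JiggleUnavailable` when the band does not fit below the
    native Nyquist (e.g. 5 Hz legacy tags) — callers fall back to OCDR.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ParameterError("jiggle band must satisfy 0 < lo < hi")
    if hi >= native_rate / 2:
        raise JiggleUnavailable(
            f"jiggle band {band} Hz infeasible at native rate {native_rate} Hz"
        )
    acc = np.asarray(native_accel, dtype=float)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=native_rate, output="sos")
    bp = signal.sosfiltfilt(sos, acc, axis=0)
    power = (bp ** 2).sum(axis=1)
    w = max(1, int(round(window * native_rate)))
    kernel = np.ones(w) / w
    rms = np.sqrt(np.convolve(power, kernel, mode="same"))
    if out_rate is None:
        return rms, native_rate
    t_native = np.arange(rms.size) / native_rate
    n_out = int(np.floor(t_native[-1] * out_rate)) + 1
    t_out = np.arange(n_out) / out_rate
    return np.interp(t_out, t_native, rms), out_rate


def calibrate_jiggle_speed(
    jiggle: np.ndarray,
    ocdr: SpeedSeries,
    min_pairs: int = 50,
) -> SpeedSeries:
    """Calibrate jiggle RMS into speed against OCDR.

    Ordinary least squares of OCDR speed on ``ln(jiggle RMS)`` over co-valid
    samples; the fit is then applied to *every* jiggle sample (clipped at 0)
    to give a continuous speed series.  The calibration dict carries slope,
    intercept and r_squared.
    """
    jiggle = np.asarray(jiggle, dtype=float)
    if jiggle.shape != ocdr.speed.shape:
        raise ParameterError("jiggle and OCDR series must be co-sampled")
    with np.errstate(divide="ignore", invalid="ignore"):
        lj = np.log(np.where(jiggle > 0, jiggle, np.nan))
    ok = np.isfinite(lj) & np.isfinite(ocdr.speed)
    if ok.sum() < min_pairs:
        raise CalibrationError(
            f"only {int(ok.sum())} co-valid jiggle/OCDR samples (< {min_pairs})"
        )
    x, y = lj[ok], ocdr.speed[ok]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    speed = np.clip(slope * lj + intercept, 0.0, None)
    cal = {"slope": float(slope), "intercept": float(intercept),
           "r_squared": float(r2), "n_pairs": int(ok.sum())}
    return SpeedSeries(speed, ocdr.rate, source="jiggle", calibration=cal)


# ---------------------------------------------------------------------------
# Minimum specific acceleration
# ---------------------------------------------------------------------------

def compute_msa(accel: np.ndarray, rate: float) -> MsaSeries:
    """MSA = ``| ||accel|| - 1 | * g`` per sample (accel in g units).

    By the reverse triangle inequality this never exceeds the magnitude of
    the true specific acceleration, hence "minimum".
    """
    norm = np.linalg.norm(np.asarray(accel, dtype=float), axis=-1)
    return MsaSeries(np.abs(norm - 1.0) * GRAVITY, rate)
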