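"""Dive detection, phase segmentation, fluking/glide and breath detection,
neutral-buoyancy estimation, and diel (day/night) assignment.

A *dive* is a maximal interval in which depth exceeds a surface threshold
(default 2 m) and reaches at least the minimum dive depth (10 m).  Phases
split at the bottom band: descent ends when depth first enters the band
``[max_depth * (1 - tol), max_depth]`` and ascent starts when it last leaves
it.  The neutral-buoyancy proxy is the depth at which fluking (oscillatory
power in the stroke band of the dynamic acceleration) ceases and a sustained
glide begins, averaged between descent and ascent and taken as a median over
dives.

Day/night follows the civil-twilight convention: night wherever the solar
elevation is below -6 deg (the boundary itself counts as day).  Solar
elevation comes from the standard NOAA fractional-year / equation-of-time /
declination formulas, accurate to well under a degree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import timedelta, timezone

import numpy as np
import pandas as pd
from scipy import signal

from .tag_io import Channel, Deployment, ParameterError, CalibrationError, _runs_of

__all__ = [
    "DiveRecord",
    "BuoyancyEstimate",
    "detect_dives",
    "segment_phases",
    "detect_fluking",
    "estimate_neutral_buoyancy",
    "detect_breaths",
    "solar_elevation_deg",
    "assign_diel",
    "hourly_rates",
]

log = logging.getLogger(__name__)


@dataclass
class DiveRecord:
    dive_id: int
    t_start: float
    t_end: float
    max_depth: float
    descent_end_t: float = np.nan
    ascent_start_t: float = np.nan
    descent_rate: float = np.nan
    ascent_rate: float = np.nan
    descent_speed: float = np.nan
    ascent_speed: float = np.nan
    n_lunges: int = 0
    n_breaths_after: int = 0
    diel: str = ""
    glide_onset_depth_descent: float = np.nan
    glide_onset_depth_ascent: float = np.nan

    @property
    def submerged_time(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BuoyancyEstimate:
    descent_cessation_depths: np.ndarray
    ascent_cessation_depths: np.ndarray
    neutral_depth: float
    n_dives: int = 0


# ---------------------------------------------------------------------------
# Dives and phases
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, rate: float, seconds: float) -> np.ndarray:
    w = max(1, int(round(seconds * rate)))
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def detect_dives(
    depth: Channel,
    min_depth: float = 10.0,
    surface_threshold: float = 2.0,
    smooth_s: float = 0.5,
) -> list[DiveRecord]:
    """Maximal intervals above the surface threshold reaching ``min_depth``."""
    z = _smooth(depth.data, depth.rate, smooth_s)
    sub = z > surface_threshold
    dives: list[DiveRecord] = []
    n = z.size
    i = 0
    while i < n:
        if sub[i]:
            j = i
            while j < n and sub[j]:
                j += 1
            if np.max(z[i:j]) >= min_depth:
                dives.append(DiveRecord(
                    dive_id=len(dives),
                    t_start=i / depth.rate,
                    t_end=(j - 1) / depth.rate,
                    max_depth=float(np.max(depth.data[i:j])),
                ))
            i = j
        else:
            i += 1
    return dives


def segment_phases(
    dive: DiveRecord,
    depth: Channel,
    tol_band: float = 0.15,
) -> tuple[float, float]:
    """Descent-end / ascent-start as first-entry / last-exit of the bottom band.

    The band is ``[max_depth * (1 - tol_band), max_depth]``.  A V-shaped dive
    yields a zero-length bottom phase at the depth maximum.  The boundaries
    are also written onto ``dive``.
    """
    i0 = int(round(dive.t_start * depth.rate))
    i1 = int(round(dive.t_end * depth.rate)) + 1
    z = depth.data[i0:i1]
    zmax = float(z.max())
    band = z >= zmax * (1.0 - tol_band)
    idx = np.flatnonzero(band)
    descent_end = dive.t_start + idx[0] / depth.rate
    ascent_start = dive.t_start + idx[-1] / depth.rate
    dive.descent_end_t = descent_end
    dive.ascent_start_t = ascent_start
    # depth-change rates over the transit phases
    if descent_end > dive.t_start:
        dive.descent_rate = (z[idx[0]] - z[0]) / (descent_end - dive.t_start)
    if dive.t_end > ascent_start:
        dive.ascent_rate = (z[idx[-1]] - z[-1]) / (dive.t_end - ascent_start)
    return descent_end, ascent_start


# ---------------------------------------------------------------------------
# Fluking / glides / neutral buoyancy
# ---------------------------------------------------------------------------

def detect_fluking(
    dynamic_accel: np.ndarray,
    rate: float,
    dives: list[DiveRecord],
    depth: Channel,
    stroke_band: tuple[float, float] = (0.3, 1.0),
    power_frac: float = 0.05,
    min_glide_s: float = 10.0,
    window_s: float = 4.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fluking mask and per-dive glide-onset depths.

    Fluking is declared where the sliding-window power of the stroke-band
    dynamic acceleration exceeds ``power_frac`` of the dive's maximum window
    power.  The descent glide onset is the depth of the last fluking sample
    before the first sustained (>= ``min_glide_s``) glide of the descent
    phase; the ascent onset is its mirror image (last fluking sample before
    the final sustained glide of the ascent).  Dives without detectable
    fluking are excluded and logged.
    """
    lo, hi = stroke_band
    if hi >= rate / 2:
        raise ParameterError(f"stroke band {stroke_band} exceeds Nyquist ({rate/2})")
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=rate, output="sos")
    bp = signal.sosfiltfilt(sos, np.asarray(dynamic_accel, dtype=float), axis=0)
    power = (bp ** 2).sum(axis=1) if bp.ndim == 2 else bp ** 2
    power = _smooth(power, rate, window_s)

    fluke_mask = np.zeros(power.size, dtype=bool)
    rows = []
    min_run = max(1, int(round(min_glide_s * rate)))
    for dive in dives:
        i0 = int(round(dive.t_start * rate))
        i1 = min(int(round(dive.t_end * rate)) + 1, power.size)
        p = power[i0:i1]
        pmax = p.max() if p.size else 0.0
        if pmax <= 0:
            log.info("dive %d: no stroke-band power; excluded from buoyancy",
                     dive.dive_id)
            continue
        mask = p >= power_frac * pmax
        fluke_mask[i0:i1] = mask
        if not mask.any():
            log.info("dive %d: all-glide; excluded from buoyancy", dive.dive_id)
            continue
        row = {"dive_id": dive.dive_id,
               "descent_onset_depth": np.nan, "ascent_onset_depth": np.nan}
        de = dive.descent_end_t
        asc = dive.ascent_start_t
        if np.isfinite(de):
            k1 = int(round((de - dive.t_start) * rate))
            row["descent_onset_depth"] = _onset_depth(
                mask[:k1], depth, i0, rate, min_run, side="descent")
        if np.isfinite(asc):
            k2 = int(round((asc - dive.t_start) * rate))
            row["ascent_onset_depth"] = _onset_depth(
                mask[k2:], depth, i0 + k2, rate, min_run, side="ascent")
        if np.isfinite(row["descent_onset_depth"]):
            dive.glide_onset_depth_descent = row["descent_onset_depth"]
        if np.isfinite(row["ascent_onset_depth"]):
            dive.glide_onset_depth_ascent = row["ascent_onset_depth"]
        rows.append(row)
    return fluke_mask, pd.DataFrame(
        rows, columns=["dive_id", "descent_onset_depth", "ascent_onset_depth"])


def _onset_depth(mask: np.ndarray, depth: Channel, offset: int, rate: float,
                 min_run: int, side: str) -> float:
    """Depth at the last fluking sample adjacent to a sustained glide run."""
    if mask.size == 0:
        return np.nan
    glide_runs = _runs_of(~mask, min_run)
    if not glide_runs.any():
        return np.nan
    if side == "descent":
        g0 = int(np.flatnonzero(glide_runs)[0])         # first sustained glide
        fl = np.flatnonzero(mask[:g0])
        if fl.size == 0:
            return np.nan
        k = int(fl[-1])
    else:
        g1 = int(np.flatnonzero(glide_runs)[-1])        # last sustained glide
        start = g1
        while start > 0 and glide_runs[start - 1]:
            start -= 1
        fl = np.flatnonzero(mask[:start])
        if fl.size == 0:
            return np.nan
        k = int(fl[-1])
    j = offset + k
    j_d = min(int(round(j / rate * depth.rate)), depth.data.size - 1)
    return float(depth.data[j_d])


def estimate_neutral_buoyancy(onsets: pd.DataFrame) -> BuoyancyEstimate:
    """Median over dives of the per-dive mean of the two cessation depths."""
    ok = onsets.dropna(subset=["descent_onset_depth", "ascent_onset_depth"])
    if len(ok) < 3:
        raise CalibrationError(
            f"only {len(ok)} dives with both glide onsets (need >= 3)")
    desc = ok["descent_onset_depth"].to_numpy(dtype=float)
    asc = ok["ascent_onset_depth"].to_numpy(dtype=float)
    per_dive = (desc + asc) / 2.0
    return BuoyancyEstimate(
        descent_cessation_depths=desc,
        ascent_cessation_depths=asc,
        neutral_depth=float(np.median(per_dive)),
        n_dives=len(ok),
    )


# ---------------------------------------------------------------------------
# Breaths
# ---------------------------------------------------------------------------

def detect_breaths(
    depth: Channel,
    exhale_envelope: Channel | None = None,
    max_depth: float = 0.5,
    min_spacing_s: float = 2.0,
    min_prominence: float = 0.15,
    envelope_tol_s: float = 1.0,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Breath timestamps: shallow depth minima, optionally envelope-gated.

    Local depth minima shallower than ``max_depth`` m, separated by at least
    ``min_spacing_s``, with prominence >= ``min_prominence``.  When an
    exhalation-envelope channel is supplied, every breath must coincide
    (within ``envelope_tol_s``) with an envelope pulse, and at most one
    breath is kept per pulse.
    """
    z = _smooth(depth.data, depth.rate, smooth_s)
    if exhale_envelope is None:
        dist = max(1, int(round(min_spacing_s * depth.rate)))
        peaks, _ = signal.find_peaks(-z, height=-max_depth, distance=dist,
                                     prominence=min_prominence)
        return peaks / depth.rate
    env = exhale_envelope.data
    thr = max(0.3, 5.0 * float(np.median(env)))
    pk, _ = signal.find_peaks(env, height=thr,
                              distance=max(1, int(exhale_envelope.rate)))
    pulses = pk / exhale_envelope.rate
    out: list[float] = []
    w = max(1, int(round(envelope_tol_s * depth.rate)))
    for t_p in pulses:
        k = int(round(t_p * depth.rate))
        sl = slice(max(0, k - w), min(z.size, k + w + 1))
        if sl.start >= sl.stop:
            continue
        zmin = float(z[sl].min())
        if zmin < max_depth:
            # breath at the shallowest point near the pulse (the pulse time
            # itself on a flat surface trace)
            k_min = sl.start + int(np.argmin(z[sl]))
            t_b = k_min / depth.rate
            if abs(float(z[k]) - zmin) < 1e-12:
                t_b = t_p
            if not out or t_b - out[-1] >= min_spacing_s:
                out.append(t_b)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Diel assignment (NOAA solar position)
# ---------------------------------------------------------------------------

def solar_elevation_deg(when_utc, latitude: float, longitude: float) -> float:
    """Geometric solar elevation (degrees) from the NOAA equations."""
    doy = when_utc.timetuple().tm_yday
    frac_h = when_utc.hour + when_utc.minute / 60 + when_utc.second / 3600
    gamma = 2 * math.pi / 365 * (doy - 1 + (frac_h - 12) / 24)
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(gamma)
                       - 0.032077 * math.sin(gamma)
                       - 0.014615 * math.cos(2 * gamma)
                       - 0.040849 * math.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))
    time_offset = eqtime + 4 * longitude                 # minutes, UTC basis
    tst = frac_h * 60 + time_offset
    ha = math.radians(tst / 4 - 180)
    lat = math.radians(latitude)
    cos_zen = (math.sin(lat) * math.sin(decl)
               + math.cos(lat) * math.cos(decl) * math.cos(ha))
    return 90.0 - math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))


def assign_diel(
    times_s: np.ndarray,
    deployment: Deployment | None = None,
    twilight_table: pd.DataFrame | None = None,
    threshold_deg: float = -6.0,
) -> np.ndarray:
    """Label seconds-since-tag-on timestamps as ``"day"`` or ``"night"``.

    Night wherever the solar elevation is strictly below ``threshold_deg``
    (civil twilight, -6 deg); the boundary itself is day.  An explicit
    twilight table (columns ``sunrise_twilight``, ``sunset_twilight`` in
    seconds since tag-on, one row per day cycle) overrides the astronomical
    computation.
    """
    times_s = np.atleast_1d(np.asarray(times_s, dtype=float))
    if twilight_table is not None:
        labels = np.full(times_s.size, "night", dtype=object)
        for _, row in twilight_table.iterrows():
            rise, set_ = float(row["sunrise_twilight"]), float(row["sunset_twilight"])
            labels[(times_s >= rise) & (times_s < set_)] = "day"
        return labels.astype(str)
    if deployment is None:
        raise ParameterError("assign_diel needs a deployment or a twilight table")
    out = np.empty(times_s.size, dtype=object)
    utc = timezone.utc
    for i, t in enumerate(times_s):
        when = (deployment.tag_on + timedelta(seconds=float(t))).astimezone(utc)
        elev = solar_elevation_deg(when, deployment.latitude, deployment.longitude)
        out[i] = "night" if elev < threshold_deg else "day"
    return out.astype(str)


# ---------------------------------------------------------------------------
# Hourly rates
# ---------------------------------------------------------------------------

def hourly_rates(
    event_times_s: np.ndarray,
    deployment: Deployment,
    twilight_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Median (range) of events per complete clock hour, split day/night.

    Clock hours are local-time aligned; the partial first and last hours of
    the deployment are discarded.  The hour containing the evening twilight
    crossing counts as night, the hour containing the morning crossing as
    day; other hours take the label of their midpoint.
    """
    total = deployment.duration_s
    if total < 2 * 3600.0:
        log.warning("deployment shorter than two complete hours; empty rate table")
        return pd.DataFrame(columns=["diel", "median", "min", "max", "n_hours"])
    # first complete local clock hour after tag-on
    frac = (deployment.tag_on.minute * 60 + deployment.tag_on.second)
    start = (3600 - frac) % 3600
    edges = np.arange(start, total + 1e-9, 3600.0)
    if len(edges) < 2:
        return pd.DataFrame(columns=["diel", "median", "min", "max", "n_hours"])
    ev = np.asarray(event_times_s, dtype=float)
    labels, counts = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > total + 1e-9:
            break
        mids = assign_diel(np.array([a, (a + b) / 2, b]), deployment,
                           twilight_table)
        if mids[0] == "day" and mids[2] == "night":
            lab = "night"            # hour containing sunset -> night
        elif mids[0] == "night" and mids[2] == "day":
            lab = "day"              # hour containing sunrise -> day
        else:
            lab = mids[1]
        labels.append(lab)
        counts.append(int(((ev >= a) & (ev < b)).sum()))
    df = pd.DataFrame({"diel": labels, "count": counts})
    rows = []
    for lab, g in df.groupby("diel"):
        c = g["count"].to_numpy()
        rows.append({"diel": lab, "median": float(np.median(c)),
                     "min": int(c.min()), "max": int(c.max()),
                     "n_hours": int(len(c))})
    return pd.DataFrame(rows)
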