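"""Circling and lunge detection, circle-lunge linking and event profiles.

Circling is a continuous >= 180 deg heading rotation in one direction at
near-level pitch (|pitch| < 85 deg, avoiding gimbal lock); lunges are sharp
speed peaks followed by a rapid deceleration below the pre-lunge baseline.
Circles that are not followed by a lunge within a configurable gap are
counted as presumed failed foraging attempts.

Heading is unwrapped with shortest-arc increments; rotation segmentation
uses a reversal-tolerant swing decomposition: the cumulative rotation series
is split at every counter-rotation exceeding ``reversal_tol``, and each
monotone swing whose total rotation reaches the threshold (and lasts at
least ``min_duration``) is one circling event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tag_io import ParameterError
from .dive_phases import DiveRecord

__all__ = [
    "CircleEvent",
    "LungeEvent",
    "unwrap_heading",
    "detect_circling",
    "detect_lunges",
    "link_attempts",
    "classify_lunge_context",
    "average_event_profile",
]


@dataclass
class CircleEvent:
    t_start: float
    t_end: float
    total_rotation: float       # degrees, signed (+ clockwise)
    mean_depth: float = np.nan
    followed_by_lunge: bool = False
    end_speed_ratio: float = np.nan

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class LungeEvent:
    t_peak: float
    depth_at_peak: float
    peak_speed: float
    pre_speed: float
    decel: float
    max_roll: float = np.nan    # degrees
    surface: bool = False
    preceded_by_circle: bool = False


# ---------------------------------------------------------------------------
# Circling
# ---------------------------------------------------------------------------

def unwrap_heading(heading: np.ndarray) -> np.ndarray:
    """Shortest-arc unwrapping of a (possibly NaN-masked) heading series."""
    h = np.asarray(heading, dtype=float)
    out = np.full_like(h, np.nan)
    ok = np.isfinite(h)
    if ok.any():
        out[ok] = np.unwrap(h[ok])
    return out


def _swings(cum: np.ndarray, tol: float) -> list[tuple[int, int, float]]:
    """Reversal-tolerant swing decomposition of a cumulative-rotation series.

    A swing runs between consecutive *confirmed* extrema, where an extremum
    is confirmed once the series retraces more than ``tol`` beyond it in the
    opposite direction (indices are the first sample attaining each
    extremum).  Returns ``(i_start, i_end, rotation)`` per swing, including
    the unconfirmed final swing at the end of the series.
    """
    n = cum.size
    if n < 2:
        return []
    swings: list[tuple[int, int, float]] = []
    # Boundary convention: a swing starts at the *last* attainment of its
    # start extremum and ends at the *first* attainment of its end extremum,
    # so flat (no-rotation) stretches never pad a circling interval.
    min_f = min_l = max_f = max_l = 0    # first/last attainment of extrema
    d = 0
    k = 1
    while k < n and d == 0:
        x = cum[k]
        if x < cum[min_f]:
            min_f = min_l = k
        elif x == cum[min_f]:
            min_l = k
        if x > cum[max_f]:
            max_f = max_l = k
        elif x == cum[max_f]:
            max_l = k
        if x - cum[min_f] > tol:
            d = +1
            start_l = min_l
            cand_f, cand_l = ((max_f, max_l) if max_f > min_l else (k, k))
        elif cum[max_f] - x > tol:
            d = -1
            start_l = max_l
            cand_f, cand_l = ((min_f, min_l) if min_f > max_l else (k, k))
        k += 1
    if d == 0:
        # range never exceeded tol: no swing can reach any threshold > tol
        return []
    while k < n:
        x = cum[k]
        if d == +1:
            if x > cum[cand_f]:
                cand_f = cand_l = k
            elif x == cum[cand_f]:
                cand_l = k
            elif cum[cand_f] - x > tol:
                swings.append((start_l, cand_f, cum[cand_f] - cum[start_l]))
                start_l = cand_l
                cand_f = cand_l = k
                d = -1
        else:
            if x < cum[cand_f]:
                cand_f = cand_l = k
            elif x == cum[cand_f]:
                cand_l = k
            elif x - cum[cand_f] > tol:
                swings.append((start_l, cand_f, cum[cand_f] - cum[start_l]))
                start_l = cand_l
                cand_f = cand_l = k
                d = +1
        k += 1
    if cand_f > start_l:
        swings.append((start_l, cand_f, cum[cand_f] - cum[start_l]))
    return swings


def detect_circling(
    heading: np.ndarray,
    pitch: np.ndarray,
    rate: float,
    min_rotation: float = 180.0,
    max_abs_pitch: float = 85.0,
    reversal_tol: float = 30.0,
    min_duration: float = 3.0,
    depth: np.ndarray | None = None,
    speed: np.ndarray | None = None,
    pause_rate: float = 2.0,
    max_pause: float = 10.0,
) -> list[CircleEvent]:
    """Detect circling events (continuous >= ``min_rotation`` deg rotations).

    The heading series is unwrapped over runs of valid pitch
    (|pitch| < ``max_abs_pitch`` deg); each run is decomposed into swings
    with counter-rotation tolerance ``reversal_tol`` (degrees), and swings
    with |rotation| >= ``min_rotation`` lasting >= ``min_duration`` seconds
    become events.

    "Continuous" rotation also means without long standstills: sustained
    runs (>= ``max_pause`` s) in which the smoothed turn rate stays below
    ``pause_rate`` deg/s split the series, so separate maneuvers minutes
    apart can never accumulate into one nominal rotation.  Set
    ``pause_rate=0`` to disable.
    """
    heading = np.asarray(heading, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    valid = np.isfinite(heading) & np.isfinite(pitch) & (
        np.abs(pitch) < np.deg2rad(max_abs_pitch))
    if pause_rate > 0 and heading.size > 2:
        from .tag_io import _runs_of
        cont = unwrap_heading(heading)
        ok = np.isfinite(cont)
        if ok.any() and not ok.all():
            idx = np.arange(cont.size)
            cont = np.interp(idx, idx[ok], cont[ok])
        # net rotation rate over a +/-1 s span (sign-averaging kills the
        # sample-to-sample magnetometer noise before rectification)
        w = max(1, int(round(1.0 * rate)))
        padded = np.pad(cont, w, mode="edge")
        turn = np.abs(padded[2 * w:] - padded[:-2 * w]) * rate / (2.0 * w)
        pause = _runs_of(turn < np.deg2rad(pause_rate),
                         max(1, int(round(max_pause * rate))))
        valid &= ~pause
    tol = np.deg2rad(reversal_tol)
    events: list[CircleEvent] = []
    n = heading.size
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        cum = np.unwrap(heading[i:j])
        for a, b, rot in _swings(cum, tol):
            dur = (b - a) / rate
            if abs(rot) >= np.deg2rad(min_rotation) and dur >= min_duration:
                ev = CircleEvent(
                    t_start=(i + a) / rate,
                    t_end=(i + b) / rate,
                    total_rotation=float(np.rad2deg(rot)),
                )
                if depth is not None:
                    ev.mean_depth = float(np.nanmean(depth[i + a:i + b + 1]))
                if speed is not None:
                    seg = speed[i + a:i + b + 1]
                    q = max(1, seg.size // 4)
                    first = float(np.nanmean(seg[:q]))
                    last = float(np.nanmean(seg[-q:]))
                    ev.end_speed_ratio = last / first if first > 0 else np.nan
                events.append(ev)
        i = j
    return events


# ---------------------------------------------------------------------------
# Lunges
# ---------------------------------------------------------------------------

def detect_lunges(
    speed: np.ndarray,
    rate: float,
    dives: list[DiveRecord] | None = None,
    pitch: np.ndarray | None = None,
    roll: np.ndarray | None = None,
    depth: np.ndarray | None = None,
    peak_quantile: float = 0.90,
    abs_threshold: float | None = None,
    min_decel: float = 0.2,
    min_rise: float = 1.0,
    pre_window_s: float = 15.0,
    post_window_s: float = 15.0,
    min_separation_s: float = 10.0,
) -> list[LungeEvent]:
    """Detect lunges as sharp speed peaks with rapid deceleration.

    Candidate peaks are local speed maxima above a deployment-adaptive
    threshold (the ``peak_quantile`` of in-dive speed, or ``abs_threshold``
    m/s when given) standing at least ``min_rise`` m/s above the pre-peak
    baseline.  A candidate is accepted when the maximum post-peak
    deceleration reaches ``min_decel`` m/s^2 and speed drops below the
    pre-peak baseline within ``post_window_s``.
    """
    from scipy.signal import find_peaks

    v = np.asarray(speed, dtype=float)
    n = v.size
    in_dive = np.zeros(n, dtype=bool)
    if dives:
        for d in dives:
            in_dive[int(d.t_start * rate):int(d.t_end * rate) + 1] = True
    else:
        in_dive[:] = True
    pool = v[in_dive & np.isfinite(v)]
    if pool.size == 0:
        return []
    thr = abs_threshold if abs_threshold is not None else float(
        np.quantile(pool, peak_quantile))
    vv = np.where(np.isfinite(v), v, 0.0)
    dist = max(1, int(round(min_separation_s * rate)))
    peaks, _ = find_peaks(vv, height=thr, distance=dist,
                          prominence=0.8 * min_rise)
    peaks = peaks[in_dive[peaks]]
    pre_w = int(round(pre_window_s * rate))
    post_w = int(round(post_window_s * rate))
    events: list[LungeEvent] = []
    for k in peaks:
        pre = v[max(0, k - pre_w):max(1, k - int(5 * rate))]
        pre = pre[np.isfinite(pre)]
        if pre.size == 0:
            continue
        pre_speed = float(np.median(pre))
        post = vv[k:min(n, k + post_w)]
        if post.size < 3:
            continue
        # steepest 1-s deceleration after the peak
        step = max(1, int(round(rate)))
        if post.size > step:
            decel = float(np.max((post[:-step] - post[step:]) * rate / step))
        else:
            decel = float((post[0] - post[-1]) * rate / max(post.size - 1, 1))
        if decel < min_decel or float(post.min()) >= pre_speed:
            continue
        if v[k] < pre_speed + min_rise:
            continue
        ev = LungeEvent(
            t_peak=k / rate,
            depth_at_peak=float(depth[k]) if depth is not None else np.nan,
            peak_speed=float(v[k]),
            pre_speed=pre_speed,
            decel=decel,
        )
        if roll is not None:
            sl = slice(max(0, k - post_w), min(n, k + post_w))
            ev.max_roll = float(np.rad2deg(np.nanmax(np.abs(roll[sl]))))
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Linking and context
# ---------------------------------------------------------------------------

def link_attempts(
    circles: list[CircleEvent],
    lunges: list[LungeEvent],
    max_gap: float = 30.0,
    overlap_tol: float = 15.0,
) -> tuple[pd.DataFrame, float]:
    """Link each circle to the first subsequent lunge within ``max_gap`` s.

    A lunge peaking inside the circle's final ``overlap_tol`` seconds also
    counts as following it (the acceleration into a lunge begins while the
    detected rotation is still closing).  Links are injective (one lunge per
    circle, assigned greedily in time order).  Returns the attempts table
    and the failed-attempt fraction (unlinked circles / circles).
    """
    rows = []
    used: set[int] = set()
    lunge_times = np.array([lg.t_peak for lg in lunges])
    order = np.argsort(lunge_times)
    for c in sorted(circles, key=lambda c: c.t_start):
        lo = max(c.t_start, c.t_end - overlap_tol)
        linked = None
        for idx in order:
            if idx in used:
                continue
            t = lunge_times[idx]
            if lo <= t <= c.t_end + max_gap:
                linked = int(idx)
                break
            if t > c.t_end + max_gap:
                break
        c.followed_by_lunge = linked is not None
        if linked is not None:
            used.add(linked)
            lunges[linked].preceded_by_circle = True
        rows.append({
            "circle_t_start": c.t_start, "circle_t_end": c.t_end,
            "rotation_deg": c.total_rotation,
            "lunge_t_peak": lunge_times[linked] if linked is not None else np.nan,
            "linked": linked is not None,
        })
    table = pd.DataFrame(rows)
    failed = (1.0 - table["linked"].mean()) if len(table) else np.nan
    return table, float(failed) if len(table) else np.nan


def classify_lunge_context(
    lunges: list[LungeEvent],
    dives: list[DiveRecord],
    surface_depth: float = 10.0,
    deep_depth: float = 50.0,
) -> pd.DataFrame:
    """Per-lunge context (surface / deep / midwater) and per-dive counts.

    Surface lunges have peak depth <= ``surface_depth``; deep lunges exceed
    ``deep_depth``.  Each dive's ``n_lunges`` is attached to its record; a
    foraging dive is a >= 10 m dive containing at least one lunge.  A lunge
    deeper than ``surface_depth`` lying outside every dive raises an
    integrity warning in the returned table.
    """
    for d in dives:
        d.n_lunges = 0
    rows = []
    for lg in lunges:
        home = next((d for d in dives if d.t_start <= lg.t_peak <= d.t_end), None)
        if home is not None:
            home.n_lunges += 1
        z = lg.depth_at_peak
        lg.surface = bool(z <= surface_depth)
        if z <= surface_depth:
            ctx = "surface"
        elif z > deep_depth:
            ctx = "deep"
        else:
            ctx = "midwater"
        rows.append({
            "t_peak": lg.t_peak, "depth": z, "context": ctx,
            "dive_id": home.dive_id if home is not None else -1,
            "integrity_warning": home is None and z > surface_depth,
        })
    return pd.DataFrame(
        rows, columns=["t_peak", "depth", "context", "dive_id",
                       "integrity_warning"])


# ---------------------------------------------------------------------------
# Time-locked average profiles
# ---------------------------------------------------------------------------

def average_event_profile(
    series: dict[str, np.ndarray],
    event_times: np.ndarray,
    rate: float,
    window: float = 30.0,
) -> dict[str, pd.DataFrame]:
    """Mean and 5-95% band of each series, time-locked on the event times.

    Events whose full +/- ``window``/2 does not fit inside the record are
    excluded; the number used is reported under key ``"n_events"``.
    """
    half = int(round(window / 2.0 * rate))
    times = np.asarray(event_times, dtype=float)
    lengths = {len(x) for x in series.values()}
    if len(lengths) != 1:
        raise ParameterError("all series must share one length")
    n = lengths.pop()
    centers = np.round(times * rate).astype(int)
    keep = centers[(centers - half >= 0) & (centers + half < n)]
    if keep.size < 2:
        raise ParameterError(
            f"only {keep.size} events with complete windows (need >= 2)")
    rel_t = (np.arange(-half, half + 1)) / rate
    out: dict[str, pd.DataFrame] = {"n_events": int(keep.size)}
    for name, x in series.items():
        stack = np.stack([np.asarray(x, dtype=float)[c - half:c + half + 1]
                          for c in keep])
        out[name] = pd.DataFrame({
            "t": rel_t,
            "mean": np.nanmean(stack, axis=0),
            "p05": np.nanpercentile(stack, 5, axis=0),
            "p95": np.nanpercentile(stack, 95, axis=0),
        })
    return out
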