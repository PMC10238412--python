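"""Shared fixtures: one simulated reference deployment per session, plus
independent brute-force oracles used to cross-check the detectors."""

from __future__ import annotations

import math

import numpy as np
import pytest

import whalekin as wk


@pytest.fixture(scope="session")
def demo_cfg() -> wk.SimulationConfig:
    return wk.demo_config(seed=1)


@pytest.fixture(scope="session")
def demo_sim(demo_cfg):
    """(sensors, truth) for the ~20-dive reference deployment."""
    return wk.simulate_deployment(demo_cfg)


@pytest.fixture(scope="session")
def demo_result(demo_sim):
    sensors, _ = demo_sim
    return wk.run_pipeline(sensors)


@pytest.fixture(scope="session")
def noise_free_sim():
    cfg = wk.demo_config(seed=3, duration_h=1.0).noise_free()
    return cfg, *wk.simulate_deployment(cfg)


@pytest.fixture(scope="session")
def asym_result():
    """Deployment with asymmetric glide onsets (24 m descent / 38 m ascent)."""
    cfg = wk.demo_config(seed=21, glide_onset_depth_descent=24.0,
                         glide_onset_depth_ascent=38.0)
    sensors, _ = wk.simulate_deployment(cfg)
    return wk.run_pipeline(sensors)


# ---------------------------------------------------------------------------
# Brute-force oracles (plain Python, written from the documented definitions,
# independent of the package implementations they check)
# ---------------------------------------------------------------------------

def oracle_swings(cum, tol):
    """Swing decomposition by explicit forward search for confirmed extrema.

    Boundary convention mirrored from the documented behavior: a swing
    starts at the last attainment of its start extremum and ends at the
    first attainment of its end extremum.
    """
    cum = [float(c) for c in cum]
    n = len(cum)
    if n < 2:
        return []
    # initial direction: scan until the range since the start exceeds tol
    k = 1
    d = 0
    start = ext = None
    mn_f = mn_l = mx_f = mx_l = 0
    while k < n:
        x = cum[k]
        if x < cum[mn_f]:
            mn_f = mn_l = k
        elif x == cum[mn_f]:
            mn_l = k
        if x > cum[mx_f]:
            mx_f = mx_l = k
        elif x == cum[mx_f]:
            mx_l = k
        if x - cum[mn_f] > tol:
            d, start = +1, mn_l
            ext = mx_f if mx_f > mn_l else k
            break
        if cum[mx_f] - x > tol:
            d, start = -1, mx_l
            ext = mn_f if mn_f > mx_l else k
            break
        k += 1
    if d == 0:
        return []
    out = []
    k += 1
    while k < n:
        # extend the current swing to its extremum, confirmed by a reversal
        while k < n:
            if d == +1:
                if cum[k] > cum[ext]:
                    ext = k
                elif cum[ext] - cum[k] > tol:
                    break
            else:
                if cum[k] < cum[ext]:
                    ext = k
                elif cum[k] - cum[ext] > tol:
                    break
            k += 1
        if k >= n:
            break
        out.append((start, ext, cum[ext] - cum[start]))
        # next swing starts at the last attainment of the closing extremum
        start = ext
        for j in range(ext + 1, k + 1):
            if cum[j] == cum[ext]:
                start = j
        ext = k
        d = -d
        k += 1
    if ext > start:
        out.append((start, ext, cum[ext] - cum[start]))
    return out


def oracle_circles(heading, pitch, rate, min_rotation=180.0, max_abs_pitch=85.0,
                   reversal_tol=30.0, min_duration=3.0):
    """Circling oracle: per valid-pitch run, manual shortest-arc unwrap, then
    swing search; emit swings >= min_rotation lasting >= min_duration."""
    n = len(heading)
    valid = [bool(np.isfinite(heading[i]) and np.isfinite(pitch[i])
                  and abs(pitch[i]) < math.radians(max_abs_pitch))
             for i in range(n)]
    events = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        cum = [float(heading[i])]
        for k in range(i + 1, j):
            step = float(heading[k]) - float(heading[k - 1])
            while step > math.pi:
                step -= 2 * math.pi
            while step < -math.pi:
                step += 2 * math.pi
            cum.append(cum[-1] + step)
        for a, b, rot in oracle_swings(cum, math.radians(reversal_tol)):
            if (abs(rot) >= math.radians(min_rotation)
                    and (b - a) / rate >= min_duration):
                events.append((i + a, i + b, math.degrees(rot)))
        i = j
    return events


def oracle_link(circle_bounds, lunge_times, max_gap=30.0, overlap_tol=15.0):
    """Greedy injective circle->lunge linking, brute force over all lunges."""
    lunge_times = sorted(float(t) for t in lunge_times)
    used = [False] * len(lunge_times)
    links = []
    for (t0, t1) in sorted(circle_bounds):
        lo = max(t0, t1 - overlap_tol)
        pick = None
        for idx, t in enumerate(lunge_times):
            if used[idx]:
                continue
            if lo <= t <= t1 + max_gap:
                pick = idx
                break
            if t > t1 + max_gap:
                break
        if pick is not None:
            used[pick] = True
        links.append(lunge_times[pick] if pick is not None else None)
    return links


def match_events(true_times, det_times, tol):
    """(recall, precision) with one-to-one greedy matching at |dt| <= tol."""
    true_times = np.sort(np.asarray(true_times, dtype=float))
    det_times = np.sort(np.asarray(det_times, dtype=float))
    used = np.zeros(det_times.size, dtype=bool)
    hits = 0
    for t in true_times:
        cand = np.flatnonzero((~used) & (np.abs(det_times - t) <= tol))
        if cand.size:
            used[cand[0]] = True
            hits += 1
    recall = hits / max(true_times.size, 1)
    precision = used.sum() / max(det_times.size, 1)
    return recall, precision


def random_heading_track(rng, n=300):
    """Random mix of rotation bursts, wander and pauses, wrapped to [0, 2pi)."""
    steps = []
    while sum(len(s) for s in steps) < n:
        kind = rng.integers(0, 3)
        m = int(rng.integers(10, 60))
        if kind == 0:       # rotation burst
            rate = rng.uniform(2.0, 12.0) * rng.choice([-1.0, 1.0])
            steps.append(np.full(m, math.radians(rate) / 10.0))
        elif kind == 1:     # wander
            steps.append(rng.normal(0.0, math.radians(2.0), m))
        else:               # near-pause
            steps.append(rng.normal(0.0, math.radians(0.2), m))
    inc = np.concatenate(steps)[:n]
    return np.mod(np.cumsum(inc) + rng.uniform(0, 2 * math.pi), 2 * math.pi)
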