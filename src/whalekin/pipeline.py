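"""End-to-end analysis pipeline: sensors in, dives/events/energetics out.

Order of operations mirrors how the stages depend on one another: depth
zeroing -> decimation to the analysis rate -> orientation (static/dynamic
split, pitch/roll/heading) -> speed (OCDR, jiggle calibration; OCDR-only
fallback for low-rate tags) -> MSA -> dives, phases, fluking/buoyancy,
breaths, diel -> circling/lunges/linking -> power and per-activity work ->
summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tag_io, orientation_speed as ors, dive_phases as dph
from . import foraging_events as fev, energetics as erg, summaries_stats as sst
from .tag_io import Channel, SensorSeries

__all__ = ["PipelineResult", "run_pipeline", "results_event_table"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    rate: float
    depth: Channel                       # zeroed, analysis rate
    orientation: ors.OrientationSeries
    speed: ors.SpeedSeries
    ocdr: ors.SpeedSeries
    msa: ors.MsaSeries
    dives: list
    onsets: pd.DataFrame
    buoyancy: dph.BuoyancyEstimate | None
    breath_times: np.ndarray
    diel: np.ndarray                     # per-sample day/night
    circles: list
    lunges: list
    attempts: pd.DataFrame
    failed_attempt_fraction: float
    lunge_context: pd.DataFrame
    mass: erg.MassEstimate | None
    power: np.ndarray | None
    energetics: pd.DataFrame
    summary: pd.DataFrame
    deployment: tag_io.Deployment | None = None
    extras: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.depth.data.size) / self.rate


def _common_length(series: SensorSeries, rate: float) -> int:
    return min(int(np.floor(ch.duration * rate))
               for ch in series.channels.values())


def run_pipeline(
    series: SensorSeries,
    analysis_rate: float = 10.0,
    mass_override: float | None = 6000.0,
    jiggle_band: tuple[float, float] = (10.0, 45.0),
    min_dive_depth: float = 10.0,
    surface_threshold: float = 2.0,
    declination: float = 0.0,
) -> PipelineResult:
    """Run the full kinematics + energetics analysis on one deployment.

    ``analysis_rate`` is capped at the slowest required channel (a 5 Hz
    legacy tag is analyzed at 5 Hz rather than upsampled); the jiggle speed
    proxy is replaced by gap-interpolated OCDR when the jiggle band does not
    fit below the native accelerometer Nyquist.
    """
    deployment = series.deployment
    rate = min(analysis_rate,
               *(series.channels[c].rate for c in tag_io.REQUIRED_CHANNELS))
    if rate < analysis_rate:
        log.info("analysis rate lowered to %.3g Hz (slowest channel)", rate)

    zeroed = dict(series.channels)
    zeroed["depth"] = tag_io.zero_depth_offset(series["depth"])
    ds = tag_io.downsample_series(SensorSeries(zeroed, deployment), rate)
    n = _common_length(
        SensorSeries({k: v for k, v in ds.channels.items()
                      if not k.startswith("native_")}), rate)

    accel = ds.triplet("accel")[:n]
    mag = ds.triplet("mag")[:n]
    depth = Channel(ds["depth"].data[:n], rate, "m")

    static, dynamic = ors.split_static_dynamic(accel, rate)
    pitch, roll = ors.compute_pitch_roll(static)
    heading = ors.compute_heading(pitch, roll, mag, declination=declination)
    orientation = ors.OrientationSeries(pitch, roll, heading, static, dynamic,
                                        rate)

    ocdr = ors.compute_ocdr_speed(depth.data, pitch, rate)
    if "native_accel_x" in ds:
        native = np.column_stack([ds[f"native_accel_{ax}"].data
                                  for ax in "xyz"])
        native_rate = ds["native_accel_x"].rate
    else:
        native = accel
        native_rate = rate
    try:
        jiggle, _ = ors.compute_jiggle(native, native_rate, band=jiggle_band,
                                       out_rate=rate)
        speed = ors.calibrate_jiggle_speed(jiggle[:n], ocdr)
    except (ors.JiggleUnavailable, tag_io.CalibrationError) as exc:
        log.info("jiggle speed unavailable (%s); OCDR-only fallback", exc)
        filled = ocdr.speed.copy()
        ok = np.isfinite(filled)
        if ok.any():
            idx = np.arange(filled.size)
            filled = np.interp(idx, idx[ok], filled[ok])
        speed = ors.SpeedSeries(filled, rate, source="ocdr")
    msa = ors.compute_msa(accel, rate)

    dives = dph.detect_dives(depth, min_depth=min_dive_depth,
                             surface_threshold=surface_threshold)
    for d in dives:
        dph.segment_phases(d, depth)
    fluke_mask, onsets = dph.detect_fluking(dynamic, rate, dives, depth)
    buoyancy = None
    try:
        buoyancy = dph.estimate_neutral_buoyancy(onsets)
    except tag_io.CalibrationError as exc:
        log.info("neutral buoyancy not estimated: %s", exc)
    breath_times = dph.detect_breaths(
        depth, ds.channels.get("exhale_envelope"))

    if deployment is not None:
        # label on a 1-minute grid, then broadcast to samples
        t_grid = np.arange(0.0, n / rate + 60.0, 60.0)
        grid_labels = dph.assign_diel(t_grid, deployment)
        idx = np.minimum((np.arange(n) / rate / 60.0).astype(int),
                         len(grid_labels) - 1)
        diel = grid_labels[idx]
        for d in dives:
            d.diel = str(diel[int(d.t_start * rate)])
    else:
        diel = np.full(n, "day")

    circles = fev.detect_circling(heading, pitch, rate, depth=depth.data,
                                  speed=speed.speed)
    lunges = fev.detect_lunges(speed.speed, rate, dives=dives, pitch=pitch,
                               roll=roll, depth=depth.data)
    attempts, failed_frac = fev.link_attempts(circles, lunges)
    context = fev.classify_lunge_context(lunges, dives,
                                         surface_depth=min_dive_depth)

    for d in dives:
        sl_desc = slice(int(d.t_start * rate), int(d.descent_end_t * rate) + 1)
        sl_asc = slice(int(d.ascent_start_t * rate), int(d.t_end * rate) + 1)
        with np.errstate(invalid="ignore"):
            d.descent_speed = float(np.nanmean(speed.speed[sl_desc]))
            d.ascent_speed = float(np.nanmean(speed.speed[sl_asc]))

    mass = None
    power = None
    records: list[erg.EnergeticsRecord] = []
    if deployment is not None:
        mass = erg.estimate_mass(deployment.body_length,
                                 override_mass=mass_override)
        power = erg.compute_power(mass.mass, msa, speed)
        for d in dives:
            if d.n_lunges < 1:
                continue
            c_in = [c for c in circles if d.t_start <= c.t_start <= d.t_end]
            l_in = [lg for lg in lunges if d.t_start <= lg.t_peak <= d.t_end]
            try:
                records.extend(erg.phase_energetics(d, power, rate,
                                                    circles=c_in, lunges=l_in))
            except erg.UnreliableIntervalError as exc:
                log.info("dive %d energetics skipped: %s", d.dive_id, exc)
    energetics_df = pd.DataFrame(
        [vars(r) for r in records],
        columns=["activity", "work", "peak_power", "duration", "dive_id",
                 "t_start", "t_end", "gap_frac"])

    summary = sst.dive_summary(dives, breath_times, energetics_df)
    return PipelineResult(
        rate=rate, depth=depth, orientation=orientation, speed=speed,
        ocdr=ocdr, msa=msa, dives=dives, onsets=onsets, buoyancy=buoyancy,
        breath_times=breath_times, diel=diel, circles=circles, lunges=lunges,
        attempts=attempts, failed_attempt_fraction=failed_frac,
        lunge_context=context, mass=mass, power=power,
        energetics=energetics_df, summary=summary, deployment=deployment,
        extras={"fluke_mask": fluke_mask},
    )


def results_event_table(res: PipelineResult) -> pd.DataFrame:
    """Collect detected events into a writable event table."""
    rows = []
    for t in res.breath_times:
        k = min(int(round(t * res.rate)), res.depth.data.size - 1)
        rows.append({"event_type": "breath", "t_start": float(t),
                     "depth": float(res.depth.data[k]), "attributes": {}})
    for c in res.circles:
        rows.append({"event_type": "circle", "t_start": c.t_start,
                     "t_end": c.t_end, "depth": c.mean_depth,
                     "attributes": {"rotation_deg": c.total_rotation,
                                    "followed_by_lunge": c.followed_by_lunge}})
    for lg in res.lunges:
        rows.append({"event_type": "lunge", "t_start": lg.t_peak,
                     "depth": lg.depth_at_peak,
                     "attributes": {"peak_speed": lg.peak_speed,
                                    "preceded_by_circle": lg.preceded_by_circle}})
    for d in res.dives:
        if np.isfinite(d.descent_end_t):
            rows.append({"event_type": "descent_end", "t_start": d.descent_end_t,
                         "attributes": {"dive_id": d.dive_id}})
        if np.isfinite(d.ascent_start_t):
            rows.append({"event_type": "ascent_start",
                         "t_start": d.ascent_start_t,
                         "attributes": {"dive_id": d.dive_id}})
        if np.isfinite(d.glide_onset_depth_descent):
            rows.append({"event_type": "glide_onset_descent",
                         "t_start": d.t_start,
                         "depth": d.glide_onset_depth_descent,
                         "attributes": {"dive_id": d.dive_id}})
        if np.isfinite(d.glide_onset_depth_ascent):
            rows.append({"event_type": "glide_onset_ascent",
                         "t_start": d.ascent_start_t,
                         "depth": d.glide_onset_depth_ascent,
                         "attributes": {"dive_id": d.dive_id}})
    return tag_io.make_event_table(rows)
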