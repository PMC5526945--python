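"""Filtering, segmentation and flight-parameter extraction for GPS tracks.

Raw fixes arrive at nominally 10-s intervals as ``(bird_id, day, t, x, y,
alt)`` rows in a :class:`pandas.DataFrame` with planar metre coordinates.
The pipeline is:

1. :func:`filter_fixes` — keep daylight fixes, drop misreadings;
2. :func:`segment_track` — split each bird-day into continuous flight
   sections and cut those into non-overlapping 200-s windows;
3. :func:`flight_parameters` — derive the eight per-segment flight
   parameters (AGL, horizontal displacement, elevation change, ground speed,
   vertical speed, directional variance, tailwind component and dorso-ventral
   heave amplitude) used for flight-mode classification.

Directions follow the compass convention throughout: degrees, north = 0,
clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import time
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .raster import RasterGrid
from .uplift import WindScenario

__all__ = [
    "TrackSegment",
    "FlightParams",
    "read_fixes_csv",
    "read_bursts_csv",
    "filter_fixes",
    "split_flight_sections",
    "segment_track",
    "velocity_vectors",
    "directional_variance",
    "mean_track_direction",
    "tailwind_component",
    "heave_amplitude",
    "flight_parameters",
    "segment_table",
]

FIX_COLUMNS = ["bird_id", "day", "t", "x", "y", "alt"]


@dataclass
class TrackSegment:
    """Up to ``window_s`` seconds of consecutive fixes of one bird-day."""

    fixes: pd.DataFrame
    bird_id: object
    day: object
    bursts: pd.DataFrame | None = None
    window_s: float = 200.0

    def __post_init__(self) -> None:
        t = self.fixes["t"].to_numpy()
        if len(t) and (t[-1] - t[0]) / np.timedelta64(1, "s") > self.window_s:
            raise ValueError("segment span exceeds its window")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def t_start(self):
        return self.fixes["t"].iloc[0]

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.fixes["x"].mean()), float(self.fixes["y"].mean())


@dataclass
class FlightParams:
    """The eight per-segment flight parameters."""

    agl_m: float
    horizontal_displacement_m: float
    elevation_change_m: float
    ground_speed_ms: float
    vertical_speed_ms: float
    directional_variance: float          # in [0, 1]
    tailwind_component: float            # in [-1, 1]; NaN without wind data
    heave_amplitude_g: float             # NaN when < 10 accelerometer readings


# ----------------------------------------------------------------------
# I/O

def read_fixes_csv(path) -> pd.DataFrame:
    """Read fixes from CSV columns bird_id, day, t_iso8601, x_m, y_m, alt_m."""
    df = pd.read_csv(path)
    df = df.rename(columns={"t_iso8601": "t", "x_m": "x", "y_m": "y", "alt_m": "alt"})
    df["t"] = pd.to_datetime(df["t"])
    return df[FIX_COLUMNS]


def read_bursts_csv(path) -> pd.DataFrame:
    """Read heave bursts from CSV columns bird_id, day, t_start_iso8601, s1..sN."""
    df = pd.read_csv(path)
    df = df.rename(columns={"t_start_iso8601": "t_start"})
    df["t_start"] = pd.to_datetime(df["t_start"])
    return df


def _burst_samples(bursts: pd.DataFrame) -> np.ndarray:
    cols = [c for c in bursts.columns if c.startswith("s") and c[1:].isdigit()]
    cols = sorted(cols, key=lambda c: int(c[1:]))
    return bursts[cols].to_numpy(dtype=float)


# ----------------------------------------------------------------------
# filtering

def filter_fixes(fixes: pd.DataFrame,
                 day_start: time = time(8, 0),
                 day_end: time = time(19, 30)) -> pd.DataFrame:
    """Daylight and misreading filter.

    Keeps fixes whose local time of day lies within ``[day_start, day_end]``,
    drops fixes with missing coordinates, and drops a fix whose ``x, y, alt``
    exactly repeat the previous fix of the same bird (a stuck GPS reading).
    Raises if times are not strictly increasing within a bird-day.
    """
    if fixes.empty:
        return fixes.copy()
    df = fixes.copy()
    for (_, _), grp in df.groupby(["bird_id", "day"], sort=False):
        dt = grp["t"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            raise ValueError("fix times must be strictly increasing within a bird-day")
    df = df.dropna(subset=["x", "y", "alt"])
    tod = df["t"].dt.time
    df = df[(tod >= day_start) & (tod <= day_end)]

    def _drop_repeats(grp: pd.DataFrame) -> pd.DataFrame:
        same = (grp[["x", "y", "alt"]] == grp[["x", "y", "alt"]].shift()).all(axis=1)
        return grp[~same]

    parts = [_drop_repeats(g) for _, g in df.groupby(["bird_id", "day"], sort=False)]
    return pd.concat(parts).sort_index() if parts else df.iloc[0:0]


def split_flight_sections(fixes: pd.DataFrame,
                          max_gap_s: float = 30.0,
                          slow_speed_ms: float = 1.0,
                          slow_min_s: float = 60.0) -> list[pd.DataFrame]:
    """Split one bird-day of fixes into continuous flight sections.

    A section ends where consecutive fixes are more than ``max_gap_s`` apart
    (missed fixes) or where ground speed stays below ``slow_speed_ms`` for at
    least ``slow_min_s`` (the bird is perched or walking); fixes interior to
    such a slow spell are discarded.
    """
    if len(fixes) < 2:
        return [fixes] if len(fixes) else []
    t = fixes["t"].to_numpy().astype("datetime64[ns]").astype(float) / 1e9
    dt = np.diff(t)
    dxy = np.hypot(np.diff(fixes["x"].to_numpy()), np.diff(fixes["y"].to_numpy()))
    speed = dxy / dt

    # interval i joins fix i and fix i+1; cut after fix i when the interval
    # is a gap or belongs to a sustained slow spell
    cut = dt > max_gap_s
    slow = speed < slow_speed_ms
    i = 0
    n = len(slow)
    drop_fix = np.zeros(len(fixes), bool)
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            if t[j + 1] - t[i] >= slow_min_s:
                cut[i:j + 1] = True
                drop_fix[i + 1:j + 1] = True  # keep the spell's endpoints
            i = j + 1
        else:
            i += 1

    sections: list[pd.DataFrame] = []
    start = 0
    for i in range(n):
        if cut[i]:
            sec = fixes.iloc[start:i + 1]
            sec = sec[~drop_fix[start:i + 1]]
            if len(sec):
                sections.append(sec)
            start = i + 1
    sec = fixes.iloc[start:]
    sec = sec[~drop_fix[start:]]
    if len(sec):
        sections.append(sec)
    return sections


def segment_track(fixes: pd.DataFrame,
                  window_s: float = 200.0,
                  min_fixes: int = 10,
                  bursts: pd.DataFrame | None = None,
                  **section_kwargs) -> list[TrackSegment]:
    """Cut filtered fixes into non-overlapping ``window_s`` segments.

    Windows are half-open ``[t0, t0 + window_s)`` and anchored at the first
    fix of each continuous flight section of each bird-day; windows holding
    fewer than ``min_fixes`` fixes are discarded.  When ``bursts`` is given,
    each segment collects the accelerometer bursts overlapping its window.
    """
    segments: list[TrackSegment] = []
    for (bird, day), grp in fixes.groupby(["bird_id", "day"], sort=False):
        for section in split_flight_sections(grp, **section_kwargs):
            tsec = section["t"]
            t0 = tsec.iloc[0]
            while t0 <= tsec.iloc[-1]:
                t1 = t0 + pd.Timedelta(seconds=window_s)
                win = section[(tsec >= t0) & (tsec < t1)]
                if len(win) >= min_fixes:
                    seg_bursts = None
                    if bursts is not None:
                        b = bursts[(bursts["bird_id"] == bird) & (bursts["day"] == day)]
                        dur = pd.Timedelta(seconds=20)
                        seg_bursts = b[(b["t_start"] < t1) & (b["t_start"] + dur >= t0)]
                    segments.append(TrackSegment(win, bird, day, seg_bursts, window_s))
                t0 = t1
    return segments


# ----------------------------------------------------------------------
# per-segment kinematics

def velocity_vectors(fixes: pd.DataFrame) -> pd.DataFrame:
    """Speed, compass direction and vertical rate of consecutive fix pairs.

    Returns a frame with columns ``speed_ms``, ``direction_deg`` (NaN for a
    stationary pair) and ``vertical_ms``, one row per consecutive pair.
    """
    if len(fixes) < 2:
        raise ValueError("velocity vectors need at least two fixes")
    t = fixes["t"].to_numpy().astype("datetime64[ns]").astype(float) / 1e9
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("fix times must be strictly increasing")
    dx = np.diff(fixes["x"].to_numpy())
    dy = np.diff(fixes["y"].to_numpy())
    dz = np.diff(fixes["alt"].to_numpy())
    speed = np.hypot(dx, dy) / dt
    direction = np.degrees(np.arctan2(dx, dy)) % 360.0
    direction[speed == 0] = np.nan
    return pd.DataFrame({"speed_ms": speed, "direction_deg": direction,
                         "vertical_ms": dz / dt})


def directional_variance(directions_deg: Sequence[float], angular: bool = False) -> float:
    """Circular variance ``1 - Rbar`` of a set of compass directions.

    ``Rbar`` is the mean resultant length of the direction unit vectors, so
    the result is 0 when all directions coincide and 1 when they cancel.
    With ``angular=True`` the doubled convention ``2 * (1 - Rbar)`` of the
    circular-statistics literature is returned instead.  NaN directions
    (stationary pairs) are ignored; fewer than two defined directions give
    NaN.
    """
    d = np.radians(np.asarray(directions_deg, float))
    d = d[np.isfinite(d)]
    if d.size < 2:
        return float("nan")
    rbar = np.hypot(np.sin(d).mean(), np.cos(d).mean())
    v = 1.0 - rbar
    return float(2 * v if angular else v)


def mean_track_direction(fixes: pd.DataFrame) -> float:
    """Compass direction of the mean velocity vector of a segment (deg).

    The mean vector averages the horizontal velocity components of all
    consecutive-fix pairs; NaN when the mean vector is null.
    """
    vv = velocity_vectors(fixes)
    rad = np.radians(vv["direction_deg"].to_numpy())
    sp = vv["speed_ms"].to_numpy()
    ok = np.isfinite(rad)
    if not ok.any():
        return float("nan")
    vx = (sp[ok] * np.sin(rad[ok])).mean()
    vy = (sp[ok] * np.cos(rad[ok])).mean()
    if vx == 0 and vy == 0:
        return float("nan")
    return float(np.degrees(np.arctan2(vx, vy)) % 360.0)


def tailwind_component(mean_direction_deg: float, wind: WindScenario) -> float:
    """Cosine of the angle between the track and the downwind direction.

    +1 when flying exactly downwind, -1 into a headwind; unitless in
    ``[-1, 1]``.  NaN when the mean track direction is undefined.
    """
    if not math.isfinite(mean_direction_deg):
        return float("nan")
    return float(math.cos(math.radians(mean_direction_deg - wind.downwind_deg)))


def heave_amplitude(bursts: pd.DataFrame | None, min_readings: int = 10) -> float:
    """Mean heave amplitude (g) of a segment's accelerometer samples.

    The amplitude of each sample is its absolute deviation from the segment
    mean of all heave samples; the statistic is the mean of those deviations.
    NaN when fewer than ``min_readings`` samples are available.
    """
    if bursts is None or len(bursts) == 0:
        return float("nan")
    samples = _burst_samples(bursts).ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size < min_readings:
        return float("nan")
    return float(np.abs(samples - samples.mean()).mean())


def flight_parameters(seg: TrackSegment, dem: RasterGrid,
                      wind: WindScenario | None = None,
                      angular: bool = False) -> FlightParams:
    """The eight flight parameters of one track segment.

    AGL subtracts the terrain elevation sampled at each fix from its GPS
    altitude and averages; elevation change and horizontal displacement are
    first-to-last differences; speeds average the consecutive-pair velocity
    vector scalars.  ``wind`` supplies the tailwind reference; without it the
    tailwind component is NaN.
    """
    f = seg.fixes
    terrain = dem.sample(np.column_stack([f["x"].to_numpy(), f["y"].to_numpy()]))
    agl = float((f["alt"].to_numpy() - terrain).mean())
    dx = float(f["x"].iloc[-1] - f["x"].iloc[0])
    dy = float(f["y"].iloc[-1] - f["y"].iloc[0])
    vv = velocity_vectors(f)
    mean_dir = mean_track_direction(f)
    return FlightParams(
        agl_m=agl,
        horizontal_displacement_m=math.hypot(dx, dy),
        elevation_change_m=float(f["alt"].iloc[-1] - f["alt"].iloc[0]),
        ground_speed_ms=float(vv["speed_ms"].mean()),
        vertical_speed_ms=float(vv["vertical_ms"].mean()),
        directional_variance=directional_variance(vv["direction_deg"], angular=angular),
        tailwind_component=(tailwind_component(mean_dir, wind)
                            if wind is not None else float("nan")),
        heave_amplitude_g=heave_amplitude(seg.bursts),
    )


def _resolve_wind(wind, t_mid) -> WindScenario | None:
    """Pick the most recent wind record at or before a segment midpoint."""
    if wind is None or isinstance(wind, WindScenario):
        return wind
    rec = wind[wind["t"] <= t_mid]
    if rec.empty:
        return None
    row = rec.iloc[-1]
    return WindScenario(float(row["direction_from_deg"]) % 360.0, float(row["speed_ms"]))


def segment_table(segments: Iterable[TrackSegment], dem: RasterGrid,
                  wind=None, angular: bool = False) -> pd.DataFrame:
    """One row per segment: identifiers, centroid and the eight parameters.

    ``wind`` may be a single :class:`WindScenario` or a time-indexed frame of
    records (columns ``t``, ``direction_from_deg``, ``speed_ms``); with a
    frame, each segment uses the most recent record at or before its window
    midpoint.
    """
    rows = []
    for seg in segments:
        t_mid = seg.t_start + pd.Timedelta(seconds=seg.window_s / 2)
        p = flight_parameters(seg, dem, _resolve_wind(wind, t_mid), angular=angular)
        cx, cy = seg.centroid
        rows.append({
            "bird_id": seg.bird_id, "day": seg.day, "t_start": seg.t_start,
            "n_fixes": len(seg), "centroid_x": cx, "centroid_y": cy,
            "agl_m": p.agl_m,
            "horizontal_displacement_m": p.horizontal_displacement_m,
            "elevation_change_m": p.elevation_change_m,
            "ground_speed_ms": p.ground_speed_ms,
            "vertical_speed_ms": p.vertical_speed_ms,
            "directional_variance": p.directional_variance,
            "tailwind_component": p.tailwind_component,
            "heave_amplitude_g": p.heave_amplitude_g,
        })
    return pd.DataFrame(rows)
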