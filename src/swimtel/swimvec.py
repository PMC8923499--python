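"""Swim-velocity decomposition: u_s = u_og − u_h, rotated into flow frame.

Consecutive position fixes define segments with a velocity over ground
u_og; the water velocity u_h is extracted at each segment's space–time
midpoint, vertically averaged under an assumed fish depth distribution
(top 1 m, top 2 m, or full depth).  The swim velocity is the vector
difference, rotated into the local flow frame defined by the depth-averaged
flow direction: longitudinal component u_s (positive downstream, negative
upstream ⇒ positive rheotaxis) and lateral component v_s.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .hydrofield import VelocityField, VerticalRange, mean_river_velocity

log = logging.getLogger(__name__)

FLOW_EPS = 1e-3  # m/s: below this, the flow frame is undefined


def make_segments(track: pd.DataFrame, max_gap: float = 20.0) -> pd.DataFrame:
    """One segment per consecutive fix pair with dt <= max_gap (s).

    Longer gaps break the chain.  u_og = displacement / dt; the midpoint is
    the spatial and temporal average of the endpoints.
    """
    track = track.sort_values("t", kind="stable")
    if len(track) < 2:
        return pd.DataFrame(
            columns=["tag_id", "t0", "t1", "x0", "y0", "x1", "y1",
                     "mid_x", "mid_y", "mid_t", "uog_u", "uog_v"]
        )
    t = track["t"].to_numpy(float)
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    dt = np.diff(t)
    ok = (dt > 0) & (dt <= max_gap)
    i = np.flatnonzero(ok)
    return pd.DataFrame(
        {
            "tag_id": track["tag_id"].iloc[0],
            "t0": t[i],
            "t1": t[i + 1],
            "x0": x[i],
            "y0": y[i],
            "x1": x[i + 1],
            "y1": y[i + 1],
            "mid_x": 0.5 * (x[i] + x[i + 1]),
            "mid_y": 0.5 * (y[i] + y[i + 1]),
            "mid_t": 0.5 * (t[i] + t[i + 1]),
            "uog_u": (x[i + 1] - x[i]) / dt[i],
            "uog_v": (y[i + 1] - y[i]) / dt[i],
        }
    )


def rotate_to_flow(us_vec: np.ndarray, flow_vec: np.ndarray):
    """Rotate swim vectors into the local flow frame.

    ``flow_vec`` is the depth-averaged water velocity defining the
    downstream direction f; u_long = u_s · f̂ (positive downstream),
    v_lat = u_s · (f̂_y, −f̂_x).  Where ‖flow‖ < FLOW_EPS the frame is
    undefined and NaN is returned.
    """
    us = np.atleast_2d(np.asarray(us_vec, float))
    fl = np.atleast_2d(np.asarray(flow_vec, float))
    spd = np.linalg.norm(fl, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = fl / spd[:, None]
    u_long = us[:, 0] * f[:, 0] + us[:, 1] * f[:, 1]
    v_lat = us[:, 0] * f[:, 1] - us[:, 1] * f[:, 0]
    bad = spd < FLOW_EPS
    u_long = np.where(bad, np.nan, u_long)
    v_lat = np.where(bad, np.nan, v_lat)
    if np.ndim(us_vec) == 1:
        return float(u_long[0]), float(v_lat[0])
    return u_long, v_lat


def swim_records(
    segments: pd.DataFrame,
    field: VelocityField,
    vranges=("top1m", "top2m", "full"),
) -> pd.DataFrame:
    """Swim velocity per (segment, vertical range): u_s = u_og − u_h.

    u_h is extracted at the segment midpoint for each vertical range; the
    rotation frame always uses the full-depth (depth-averaged) direction.
    Segments with a dry/out-of-grid midpoint are skipped (logged).
    """
    if segments.empty:
        return pd.DataFrame()
    mx = segments["mid_x"].to_numpy()
    my = segments["mid_y"].to_numpy()
    mt = segments["mid_t"].to_numpy()
    fu, fv = field.velocity(mx, my, mt, VerticalRange.FULL_DEPTH)
    frames = []
    for vr in vranges:
        vr = VerticalRange.parse(vr)
        uh_u, uh_v = field.velocity(mx, my, mt, vr)
        rec = segments.copy()
        rec["vrange"] = vr.value
        rec["uh_u"] = uh_u
        rec["uh_v"] = uh_v
        rec["us_u"] = rec["uog_u"] - uh_u
        rec["us_v"] = rec["uog_v"] - uh_v
        u_long, v_lat = rotate_to_flow(
            np.column_stack([rec["us_u"], rec["us_v"]]),
            np.column_stack([fu, fv]),
        )
        rec["u_long"] = u_long
        rec["v_lat"] = v_lat
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    wet = np.isfinite(out["uh_u"]) & np.isfinite(out["uh_v"])
    if not wet.all():
        log.warning("skipping %d segment records with dry midpoints", (~wet).sum())
        out = out[wet].reset_index(drop=True)
    return out


def swim_velocity(segment: pd.Series, field: VelocityField, vrange) -> pd.Series:
    """Single-segment convenience wrapper around :func:`swim_records`."""
    rec = swim_records(pd.DataFrame([segment]), field, vranges=(vrange,))
    if rec.empty:
        raise ValueError("segment midpoint is dry or out of grid")
    return rec.iloc[0]


def attach_covariates(
    records: pd.DataFrame,
    field: VelocityField,
    reach=None,
    utc_offset_h: float = 0.0,
    vorticity_h: float = 2.0,
    turbidity_max_gap_s: float = 1800.0,
) -> pd.DataFrame:
    """Fill per-record covariates at segment midpoints.

    Adds: hydro speed ‖u_h‖ (record's own vertical range), vorticity
    (same range), water depth, local time of day (h), mean river velocity
    u_river, and turbidity by nearest-time gauge lookup (missing beyond
    ``turbidity_max_gap_s``).
    """
    from .hydrofield import vorticity as field_vorticity

    rec = records.copy()
    rec["speed_hydro"] = np.hypot(rec["uh_u"], rec["uh_v"])
    mx, my, mt = (rec[c].to_numpy() for c in ("mid_x", "mid_y", "mid_t"))
    vort = np.full(len(rec), np.nan)
    depth = field.depth(mx, my, mt)
    for vr, ix in rec.groupby("vrange").groups.items():
        loc = rec.index.get_indexer(ix)
        vort[loc] = field_vorticity(
            field, mx[loc], my[loc], mt[loc], VerticalRange.parse(vr), h=vorticity_h
        )
    rec["vorticity"] = vort
    rec["depth"] = depth
    rec["time_of_day_h"] = ((mt / 3600.0) + utc_offset_h) % 24.0
    if reach is not None:
        u_riv = np.full(len(rec), np.nan)
        inside = (mt >= reach.times[0]) & (mt <= reach.times[-1])
        if not inside.all():
            log.warning(
                "u_river undefined for %d records (outside gauge series)",
                (~inside).sum(),
            )
        if inside.any():
            u_riv[inside] = mean_river_velocity(reach, mt[inside])
        rec["u_river"] = u_riv
        if reach.turbidity is not None:
            j = np.clip(
                np.searchsorted(reach.times, mt), 1, reach.times.size - 1
            )
            nearer = np.where(
                np.abs(reach.times[j] - mt) < np.abs(mt - reach.times[j - 1]),
                j,
                j - 1,
            )
            turb = reach.turbidity[nearer].astype(float)
            turb[np.abs(reach.times[nearer] - mt) > turbidity_max_gap_s] = np.nan
            rec["turbidity"] = turb
        else:
            rec["turbidity"] = np.nan
    else:
        rec["u_river"] = np.nan
        rec["turbidity"] = np.nan
    return rec


def track_swim_records(
    fixes: pd.DataFrame,
    field: VelocityField,
    vranges=("top1m", "top2m", "full"),
    max_gap: float = 20.0,
) -> pd.DataFrame:
    """Segments + swim records for every track in a kept-fix table."""
    out = []
    for _, g in fixes.groupby("tag_id", sort=True):
        seg = make_segments(g, max_gap=max_gap)
        if seg.empty:
            continue
        rec = swim_records(seg, field, vranges=vranges)
        if not rec.empty:
            out.append(rec)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()
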