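"""Position- and track-level quality screening.

The cascade mirrors the field workflow: fix-level filters (uncertainty,
receiver count) → endpoint truncation → clip to the analysis region and
upstream buffer → track count/residence rules → (after swim velocities
exist) a predator screen on mean swim speed.  Order matters and is fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class QCConfig:
    sd_max: float = 10.0                # m; fixes with sd > sd_max dropped
    min_receivers: int = 2              # fixes with fewer receivers dropped
    endpoint_min_receivers: int = 3     # tracks truncated to >= this at ends
    min_positions: int = 10             # tracks with fewer fixes dropped
    max_residence_s: float = 3600.0     # longer in-region residence = predator
    upstream_buffer_m: float = 30.0     # max distance upstream of the region
    predator_speed_ms: float = 0.5      # mean swim speed above this = predator
    region: BaseGeometry | None = None  # analysis polygon, planar meters

    def __post_init__(self):
        for name in ("sd_max", "min_receivers", "endpoint_min_receivers",
                     "min_positions", "max_residence_s", "predator_speed_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_region_geojson(path) -> BaseGeometry:
    with open(path) as f:
        gj = json.load(f)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    poly = shape(gj)
    if not poly.is_valid:
        raise ValueError("region polygon is not valid/simple")
    return poly


def filter_fixes(track: pd.DataFrame, qc: QCConfig) -> pd.DataFrame:
    """Drop fixes with sd > sd_max (strictly) or too few receivers."""
    keep = (track["sd"] <= qc.sd_max) & (track["n_receivers"] >= qc.min_receivers)
    return track[keep]


def truncate_track(track: pd.DataFrame, qc: QCConfig) -> pd.DataFrame:
    """Trim ends until they use >= endpoint_min_receivers receivers.

    Interior low-receiver fixes are retained.
    """
    ok = (track["n_receivers"] >= qc.endpoint_min_receivers).to_numpy()
    if not ok.any():
        return track.iloc[0:0]
    first, last = int(np.argmax(ok)), len(ok) - 1 - int(np.argmax(ok[::-1]))
    return track.iloc[first : last + 1]


def _clip_to_region(track: pd.DataFrame, qc: QCConfig) -> pd.DataFrame:
    """Keep fixes inside the region or within the upstream buffer.

    "Upstream of the start of the array" is measured along −x from the
    region's upstream (minimum-x) edge; fixes more than
    ``upstream_buffer_m`` beyond it are dropped, as are fixes outside the
    polygon downstream (below-junction analogue).
    """
    if qc.region is None:
        raise ValueError("QCConfig.region must be provided for region clipping")
    x_min = qc.region.bounds[0]
    pts = [Point(xy) for xy in zip(track["x"], track["y"])]
    inside = np.array([qc.region.covers(p) for p in pts], dtype=bool)
    upstream_ok = (track["x"].to_numpy() >= x_min - qc.upstream_buffer_m) & (
        track["x"].to_numpy() < x_min
    )
    return track[inside | upstream_ok]


def select_tracks(
    tracks: pd.DataFrame, qc: QCConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the full track-level cascade; returns (kept fixes, rejection log).

    Per track: fix-level filters → endpoint truncation → region clip →
    minimum position count → residence (predator) rule.  Every rejected
    track appears exactly once in the log with the first rule it violated.
    """
    kept, rejections = [], []
    for tag, g in tracks.groupby("tag_id", sort=True):
        g = g.sort_values("t", kind="stable")
        g = filter_fixes(g, qc)
        g = truncate_track(g, qc)
        g = _clip_to_region(g, qc)
        if len(g) < qc.min_positions:
            rejections.append({"tag_id": tag, "rule": "min_positions", "n": len(g)})
            continue
        residence = g["t"].iloc[-1] - g["t"].iloc[0]
        if residence > qc.max_residence_s:
            rejections.append(
                {"tag_id": tag, "rule": "residence_predator", "n": len(g)}
            )
            continue
        kept.append(g)
    kept_df = (
        pd.concat(kept, ignore_index=True)
        if kept
        else tracks.iloc[0:0].copy()
    )
    log_df = pd.DataFrame(rejections, columns=["tag_id", "rule", "n"])
    return kept_df, log_df


def flag_predator_by_speed(
    swim_records: pd.DataFrame, qc: QCConfig
) -> tuple[bool, float | None]:
    """(keep, mean_speed) for one track's swim records.

    Drop iff mean segment swim speed strictly exceeds ``predator_speed_ms``.
    With no records the decision is deferred (kept, None).
    """
    if swim_records is None or len(swim_records) == 0:
        return True, None
    spd = np.hypot(
        swim_records["us_u"].to_numpy(), swim_records["us_v"].to_numpy()
    )
    mean_speed = float(spd.mean())
    return mean_speed <= qc.predator_speed_ms, mean_speed


def apply_qc(tracks: pd.DataFrame, qc: QCConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pre-swim QC cascade over a fix table (tag_id, t, x, y, sd, n_receivers)."""
    return select_tracks(tracks, qc)
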