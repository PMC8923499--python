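"""Per-ping TDOA multilateration of tag positions.

Corrected detections are deduplicated (multipath echoes), associated into
transmission events, and each event with at least three distinct receivers
is located by Gauss–Newton least squares over (x, y, T): horizontal
position plus emission time, with the tag held at a fixed depth below the
surface (the array geometry cannot resolve the vertical).  Per-fix
positional uncertainty is the root of the trace of the linearized position
covariance scaled by the residual variance (distance RMS, DRMS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def dedupe_multipath(detections: pd.DataFrame, window: float = 2.5) -> pd.DataFrame:
    """Drop repeat receptions within ``window`` s of the last retained one.

    Within each (receiver, source) group, detections are scanned in time
    order; any detection closer than ``window`` to the previously retained
    detection is assumed to be a surface/bed reflection and dropped.  The
    earliest detection is always kept.
    """
    tcol = "corrected_time_s" if "corrected_time_s" in detections else "raw_time_s"
    det = detections.sort_values(["receiver_id", "source_id", tcol], kind="stable")
    keep = np.ones(len(det), bool)
    times = det[tcol].to_numpy()
    new_group = (
        (det["receiver_id"] != det["receiver_id"].shift())
        | (det["source_id"] != det["source_id"].shift())
    ).to_numpy()
    last = -np.inf
    for i in range(len(det)):
        if new_group[i]:
            last = times[i]
            continue
        if times[i] - last < window:
            keep[i] = False
        else:
            last = times[i]
    return det[keep].sort_index()


def max_propagation_delay(array: pd.DataFrame, sound_speed: float = 1470.0) -> float:
    """Largest receiver-to-receiver travel time (s)."""
    xyz = array[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    return float(d.max() / sound_speed)


def assemble_pings(
    detections: pd.DataFrame,
    array: pd.DataFrame,
    sound_speed: float = 1470.0,
    slack: float = 1.5,
) -> pd.DataFrame:
    """Cluster one tag's corrected detections into transmission events.

    Two detections join the same group iff their corrected times differ by
    less than the array's maximum propagation delay (× ``slack`` to absorb
    residual clock error).  Within a group each receiver appears at most
    once (earliest kept).  Adds a ``ping_group`` column.
    """
    if "corrected_time_s" not in detections:
        raise ValueError("assemble_pings requires corrected_time_s")
    gap = max_propagation_delay(array, sound_speed) * slack
    out = []
    for src, g in detections.groupby("source_id", sort=True):
        g = g.sort_values("corrected_time_s", kind="stable").copy()
        t = g["corrected_time_s"].to_numpy()
        grp = np.zeros(t.size, dtype=np.int64)
        if t.size:
            grp[1:] = np.cumsum(np.diff(t) >= gap)
        g["ping_group"] = [f"{src}:{k}" for k in grp]
        g = g.drop_duplicates(["ping_group", "receiver_id"], keep="first")
        out.append(g)
    return pd.concat(out, ignore_index=True) if out else detections.iloc[0:0].copy()


@dataclass
class LocateConfig:
    sound_speed: float = 1470.0
    tag_depth: float = 1.0            # m below surface, fixed
    surface_z: float = 0.0
    max_iter: int = 50
    tol: float = 1e-10                # step tolerance, m
    max_range: float = 1000.0         # reject fixes > 1 km from array centroid
    noise_floor_s: float = 5e-4       # residual-sigma floor for sd at low dof


def locate_ping(
    group: pd.DataFrame,
    array: pd.DataFrame,
    config: LocateConfig = LocateConfig(),
    init: np.ndarray | None = None,
) -> dict | None:
    """Locate one transmission event; ``None`` if rejected.

    Solves min Σ_h (corrected_time_h − T − d_h(x, y)/c)² by Gauss–Newton.
    Groups with fewer than three distinct receivers are not located (no
    track prior to lean on); they are counted upstream.
    """
    pos = array.set_index("id")
    recs = group["receiver_id"].to_numpy()
    if len(set(recs)) < 3:
        return None
    rx = pos.loc[recs, ["x", "y", "z"]].to_numpy(float)
    ct = group["corrected_time_s"].to_numpy(float)
    c = config.sound_speed
    zt = config.surface_z - config.tag_depth

    centroid = array[["x", "y"]].to_numpy().mean(axis=0)
    p = np.array(centroid if init is None else init, float)

    def ranges(p):
        return np.sqrt(
            (rx[:, 0] - p[0]) ** 2 + (rx[:, 1] - p[1]) ** 2 + (rx[:, 2] - zt) ** 2
        )

    T = float(np.min(ct - ranges(p) / c))
    converged = False
    for _ in range(config.max_iter):
        d = ranges(p)
        res = ct - T - d / c
        # Jacobian of predicted arrival wrt (x, y, T)
        J = np.empty((d.size, 3))
        J[:, 0] = (p[0] - rx[:, 0]) / (c * d)
        J[:, 1] = (p[1] - rx[:, 1]) / (c * d)
        J[:, 2] = 1.0
        try:
            step, *_ = np.linalg.lstsq(J, res, rcond=None)
        except np.linalg.LinAlgError:
            return None
        p = p + step[:2]
        T = T + step[2]
        if np.linalg.norm(step[:2]) < config.tol:
            converged = True
            break
    if not converged:
        log.debug("locate_ping: no convergence for group")
        return None
    if np.linalg.norm(p - centroid) > config.max_range:
        log.debug("locate_ping: solution %.0f m from array; rejected", np.linalg.norm(p - centroid))
        return None

    d = ranges(p)
    res = ct - T - d / c
    n = d.size
    dof = n - 3
    sigma2 = float(res @ res) / dof if dof > 0 else 0.0
    sigma2 = max(sigma2, config.noise_floor_s**2)
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ) * sigma2
    except np.linalg.LinAlgError:
        return None
    sd = float(np.sqrt(max(cov[0, 0] + cov[1, 1], 0.0)))
    return {
        "t": float(T),
        "x": float(p[0]),
        "y": float(p[1]),
        "sd": sd,
        "n_receivers": int(len(set(recs))),
    }


def locate_tag(
    detections: pd.DataFrame,
    array: pd.DataFrame,
    config: LocateConfig = LocateConfig(),
    reuse_window_s: float = 60.0,
) -> pd.DataFrame:
    """Locate every ping group of one tag, warm-starting from the last fix."""
    fixes = []
    prev = None
    prev_t = -np.inf
    grouped = sorted(
        detections.groupby("ping_group"),
        key=lambda kv: kv[1]["corrected_time_s"].min(),
    )
    for key, g in grouped:
        init = prev if (prev is not None and g["corrected_time_s"].min() - prev_t < reuse_window_s) else None
        fix = locate_ping(g, array, config, init=init)
        if fix is None:
            continue
        fix["tag_id"] = g["source_id"].iloc[0]
        fixes.append(fix)
        prev = np.array([fix["x"], fix["y"]])
        prev_t = fix["t"]
    cols = ["tag_id", "t", "x", "y", "sd", "n_receivers"]
    return pd.DataFrame(fixes, columns=cols) if fixes else pd.DataFrame(columns=cols)


def locate_all(
    detections: pd.DataFrame,
    array: pd.DataFrame,
    config: LocateConfig = LocateConfig(),
) -> pd.DataFrame:
    """Dedupe, assemble and locate all tag detections into position fixes."""
    tags = detections[detections["source_kind"] == "tag"]
    if tags.empty:
        return pd.DataFrame(columns=["tag_id", "t", "x", "y", "sd", "n_receivers"])
    tags = dedupe_multipath(tags)
    grouped = assemble_pings(tags, array, config.sound_speed)
    out = [
        locate_tag(g, array, config) for _, g in grouped.groupby("source_id", sort=True)
    ]
    fixes = pd.concat(out, ignore_index=True) if out else pd.DataFrame()
    return build_tracks(fixes)


def build_tracks(fixes: pd.DataFrame) -> pd.DataFrame:
    """Time-sort fixes per tag; duplicate timestamps keep the lower-sd fix."""
    if fixes.empty:
        return fixes
    fixes = fixes.sort_values(["tag_id", "t", "sd"], kind="stable")
    fixes = fixes.drop_duplicates(["tag_id", "t"], keep="first")
    return fixes.reset_index(drop=True)
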