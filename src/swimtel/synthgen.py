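"""Synthetic scenario generator with known ground truth.

Emulates the study system: a ~13-hydrophone array at ~70 m spacing in a
sheared single-thread channel, tags on a 5 s pulse-rate interval (PRI),
receiver clocks with piecewise-linear drift, Gaussian arrival-time noise,
sparse multipath-like corrupted detections, and fish moving with prescribed
swim behaviors (positive/negative rheotaxis, lateral swimming, passive
transport).  Every output carries a truth record so downstream stages can
be verified by parameter recovery.

Coordinates are local planar meters: x along-channel (positive downstream),
y cross-channel, z positive up with the undisturbed surface at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .hydrofield import VelocityField, VerticalRange

REFERENCE_ROLE = "reference"


@dataclass
class ChannelConfig:
    length_m: float = 400.0
    width_m: float = 50.0
    depth_m: float = 4.0
    peak_speed_ms: float = 0.5
    roughness_z0_m: float = 0.003
    tidal_amplitude_ms: float = 0.0
    tidal_period_s: float = 44712.0      # M2
    lateral_profile: str = "parabolic"   # or "uniform"
    vertical_profile: str = "log"        # or "uniform"

    def __post_init__(self):
        if self.depth_m <= 0:
            raise ValueError("channel depth must be positive")
        if self.roughness_z0_m >= self.depth_m:
            raise ValueError("roughness z0 must be smaller than depth")


@dataclass
class BehaviorConfig:
    """One prescribed swim behavior shared by a fraction of the cohort."""

    label: str = "passive"  # passive | rheotaxis_positive | rheotaxis_negative | lateral
    fraction: float = 1.0
    swim_speed: float = 0.0          # m/s unless speed_in_bl
    speed_in_bl: bool = False        # interpret swim_speed as body lengths/s
    diel_amplitude: float = 0.0      # fractional modulation of swim speed
    diel_peak_hour: float = 12.0


@dataclass
class ScenarioConfig:
    seed: int = 0
    duration_s: float = 7200.0
    n_receivers: int = 13
    nominal_spacing_m: float = 70.0
    array_jitter_sd_m: float = 0.0
    pri_s: float = 5.0
    pri_jitter_sd_s: float = 0.1
    beacon_interval_s: float = 30.0
    sound_speed_ms: float = 1470.0
    arrival_noise_sd_s: float = 2e-4
    detection_prob: float = 0.7
    corrupt_frac: float = 0.001
    corrupt_delay_range_s: tuple = (0.005, 0.050)
    dup_frac: float = 0.0            # true duplicate (multipath echo) rows
    tag_depth_m: float = 1.0
    drift_knot_interval_s: float = 3600.0
    drift_max_offset_s: float = 0.5
    drift_spec: dict | None = None   # receiver_id -> [(knot_time_s, offset_s), ...]
    n_fish: int = 30
    release_span_s: float = 600.0
    release_x_m: float = 20.0
    fork_length_mm_mean: float = 76.6
    fork_length_mm_sd: float = 3.0
    advect_vrange: str = "full"      # vertical range whose average advects fish
    dt_s: float = 0.5                # Euler step, well under the PRI
    channel: ChannelConfig = field(default_factory=ChannelConfig)
    behaviors: list = field(default_factory=lambda: [BehaviorConfig()])

    def __post_init__(self):
        if self.pri_s <= 0:
            raise ValueError("pri must be positive")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")
        if not 0 <= self.corrupt_frac < 1:
            raise ValueError("corrupt_frac must be in [0, 1)")
        fracs = sum(b.fraction for b in self.behaviors)
        if self.behaviors and abs(fracs - 1.0) > 1e-9:
            raise ValueError("behavior fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        chan = ChannelConfig(**raw.pop("channel", {}))
        behs = [BehaviorConfig(**b) for b in raw.pop("behaviors", [])]
        cfg = cls(channel=chan, **raw)
        if behs:
            cfg.behaviors = behs
            cfg.__post_init__()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(d, f)


# ---------------------------------------------------------------------------
# Receiver array
# ---------------------------------------------------------------------------

def gen_array(config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Place receivers on a staggered two-row grid along the channel.

    Adjacent receivers alternate between two lateral positions; with zero
    jitter the distance between adjacent receivers equals the nominal
    spacing exactly.  The first receiver is the sync reference; roughly
    half the units are "cabled" (clock-disciplined) and the rest
    "autonomous", mirroring a mixed field deployment.
    """
    n = config.n_receivers
    if n < 3:
        raise ValueError("need at least 3 receivers for multilateration")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ch = config.channel
    lat_off = min(ch.width_m / 4.0, config.nominal_spacing_m / 2.0 * 0.99)
    dx = np.sqrt(config.nominal_spacing_m**2 - (2 * lat_off) ** 2)
    yc = ch.width_m / 2.0
    x = config.release_x_m + 10.0 + dx * np.arange(n)
    y = yc + lat_off * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    if config.array_jitter_sd_m > 0:
        x = x + rng.normal(0, config.array_jitter_sd_m, n)
        y = y + rng.normal(0, config.array_jitter_sd_m, n)
    z = -ch.depth_m + 0.5  # mounted ~0.5 m off the bed
    n_cabled = max(1, n // 2)
    roles = [REFERENCE_ROLE] + ["cabled"] * (n_cabled - 1) + ["autonomous"] * (n - n_cabled)
    return pd.DataFrame(
        {
            "id": [f"R{i:02d}" for i in range(n)],
            "x": x,
            "y": y,
            "z": np.full(n, z),
            "role": roles,
        }
    )


# ---------------------------------------------------------------------------
# Analytic flow field on a grid
# ---------------------------------------------------------------------------

def gen_field(config: ScenarioConfig) -> VelocityField:
    """Separable sheared channel flow u(x,y,z,t) = U(t)·f_lat(y)·f_vert(z).

    The vertical profile is a log law over roughness z0 normalized to 1 at
    the surface; the lateral profile is parabolic, vanishing at the banks.
    U(t) = peak_speed + tidal_amplitude·sin(2πt/T).  v is identically 0.
    """
    ch = config.channel
    x = np.arange(0.0, ch.length_m + 2.0, 4.0)
    y = np.arange(0.0, ch.width_m + 1.0, 2.0)
    y = y[y <= ch.width_m]
    if y[-1] < ch.width_m:
        y = np.append(y, ch.width_m)
    nz = max(2, int(round(ch.depth_m / 0.27)) + 1)
    z = np.linspace(-ch.depth_m, 0.0, nz)
    if ch.tidal_amplitude_ms > 0:
        nt = max(3, int(config.duration_s / (ch.tidal_period_s / 48.0)) + 1)
    else:
        nt = 2
    t = np.linspace(0.0, config.duration_s, nt)

    U = ch.peak_speed_ms + ch.tidal_amplitude_ms * np.sin(
        2 * np.pi * t / ch.tidal_period_s
    )
    if ch.lateral_profile == "uniform":
        f_lat = np.ones_like(y)
    else:
        yc, hw = ch.width_m / 2.0, ch.width_m / 2.0
        f_lat = 1.0 - ((y - yc) / hw) ** 2
    if ch.vertical_profile == "uniform":
        f_vert = np.ones_like(z)
    else:
        zeta = np.clip(z + ch.depth_m, ch.roughness_z0_m, None)
        f_vert = np.log(zeta / ch.roughness_z0_m) / np.log(
            ch.depth_m / ch.roughness_z0_m
        )
        f_vert = np.clip(f_vert, 0.0, None)

    u = (
        U[:, None, None, None]
        * f_vert[None, :, None, None]
        * f_lat[None, None, :, None]
        * np.ones((1, 1, 1, x.size))
    )
    ds = xr.Dataset(
        {
            "u": (("t", "z", "y", "x"), u),
            "v": (("t", "z", "y", "x"), np.zeros_like(u)),
            "bed": (("y", "x"), np.full((y.size, x.size), -ch.depth_m)),
            "surface": (("t", "y", "x"), np.zeros((t.size, y.size, x.size))),
        },
        coords={"t": t, "z": z, "y": y, "x": x},
        attrs={"description": "synthetic sheared channel flow"},
    )
    return VelocityField(ds)


# ---------------------------------------------------------------------------
# Fish tracks
# ---------------------------------------------------------------------------

def _swim_vectors(behavior: BehaviorConfig, uh, vh, side, speeds, t):
    """Per-fish swim vector given local depth-averaged flow (uh, vh)."""
    spd = np.hypot(uh, vh)
    with np.errstate(invalid="ignore", divide="ignore"):
        fx = np.where(spd > 1e-9, uh / spd, 1.0)
        fy = np.where(spd > 1e-9, vh / spd, 0.0)
    s = speeds.copy()
    if behavior.diel_amplitude:
        hour = (t / 3600.0) % 24.0
        s = s * (
            1.0
            + behavior.diel_amplitude
            * np.cos(2 * np.pi * (hour - behavior.diel_peak_hour) / 24.0)
        )
    if behavior.label == "passive":
        return np.zeros_like(uh), np.zeros_like(vh)
    if behavior.label == "rheotaxis_positive":
        return -s * fx, -s * fy
    if behavior.label == "rheotaxis_negative":
        return s * fx, s * fy
    if behavior.label == "lateral":
        # perpendicular to flow, flipping near the banks to stay wetted
        return s * side * -fy, s * side * fx
    raise ValueError(f"unknown behavior label {behavior.label!r}")


def simulate_fish(field: VelocityField, config: ScenarioConfig, seed=None) -> pd.DataFrame:
    """Integrate fish tracks through the field with prescribed behaviors.

    Fixed-step Euler: dx = (u_h + u_swim)·dt with dt = config.dt_s.  u_h is
    the vertically averaged flow for ``config.advect_vrange``.  Tracks end
    when a fish leaves the wetted domain or the scenario ends.  Returns one
    DataFrame with columns tag_id, t, x, y, swim_u, swim_v, behavior,
    fork_length_mm sampled at every step.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ch = config.channel
    n = config.n_fish
    vrange = VerticalRange.parse(config.advect_vrange)

    # behavior assignment by configured fractions (deterministic counts)
    counts = np.floor(np.array([b.fraction for b in config.behaviors]) * n).astype(int)
    while counts.sum() < n:
        counts[np.argmax([b.fraction for b in config.behaviors])] += 1
    labels = np.repeat(np.arange(len(config.behaviors)), counts)[:n]

    fl = rng.normal(config.fork_length_mm_mean, config.fork_length_mm_sd, n)
    fl = np.clip(fl, 40.0, None)
    speeds = np.array(
        [
            b.swim_speed * (fl[i] / 1000.0 if b.speed_in_bl else 1.0)
            for i, b in enumerate(config.behaviors[j] for j in labels)
        ]
    )
    release_t = np.sort(rng.uniform(0.0, config.release_span_s, n))
    x = np.full(n, config.release_x_m) + rng.uniform(-2, 2, n)
    y = ch.width_m * rng.uniform(0.35, 0.65, n)
    side = rng.choice([-1.0, 1.0], n)
    margin = 3.0

    dt = config.dt_s
    nsteps = int(np.ceil(config.duration_s / dt))
    active = np.zeros(n, bool)
    done = np.zeros(n, bool)
    rows = {k: [] for k in ("tag", "t", "x", "y", "su", "sv", "beh")}

    for k in range(nsteps + 1):
        t = k * dt
        active = (~done) & (release_t <= t)
        if not active.any():
            if done.all():
                break
            continue
        xa, ya = x[active], y[active]
        uh, vh = field.velocity(xa, ya, np.full(xa.shape, t), vrange)
        wet = np.isfinite(uh) & np.isfinite(vh)
        if not wet.all():
            idx = np.flatnonzero(active)[~wet]
            done[idx] = True
            active[idx] = False
            xa, ya, uh, vh = xa[wet], ya[wet], uh[wet], vh[wet]
            if xa.size == 0:
                continue
        ai = np.flatnonzero(active)
        # lateral swimmers flip heading near banks
        near_hi = ya > ch.width_m - margin
        near_lo = ya < margin
        side[ai[near_hi]] = -1.0
        side[ai[near_lo]] = 1.0
        su = np.zeros_like(uh)
        sv = np.zeros_like(vh)
        for j, beh in enumerate(config.behaviors):
            m = labels[ai] == j
            if m.any():
                su[m], sv[m] = _swim_vectors(
                    beh, uh[m], vh[m], side[ai][m], speeds[ai][m], t
                )
        for key, val in zip(
            ("tag", "t", "x", "y", "su", "sv", "beh"),
            (ai, np.full(ai.size, t), xa, ya, su, sv, labels[ai]),
        ):
            rows[key].append(val)
        x[ai] = xa + (uh + su) * dt
        y[ai] = ya + (vh + sv) * dt
        out = (x[ai] < 0) | (x[ai] > ch.length_m) | (y[ai] < 0) | (y[ai] > ch.width_m)
        done[ai[out]] = True

    if not rows["t"]:
        return pd.DataFrame(
            columns=["tag_id", "t", "x", "y", "swim_u", "swim_v", "behavior",
                     "fork_length_mm"]
        )
    tag_idx = np.concatenate(rows["tag"])
    df = pd.DataFrame(
        {
            "tag_id": [f"F{i:03d}" for i in tag_idx],
            "t": np.concatenate(rows["t"]),
            "x": np.concatenate(rows["x"]),
            "y": np.concatenate(rows["y"]),
            "swim_u": np.concatenate(rows["su"]),
            "swim_v": np.concatenate(rows["sv"]),
            "behavior": [config.behaviors[j].label for j in np.concatenate(rows["beh"])],
            "fork_length_mm": fl[tag_idx],
        }
    )
    return df.sort_values(["tag_id", "t"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clock drift truths
# ---------------------------------------------------------------------------

def random_drift_spec(config: ScenarioConfig, array: pd.DataFrame, rng=None) -> dict:
    """Piecewise-linear clock-offset truths, one per receiver.

    Knots are aligned to multiples of the drift knot interval; offsets are
    bounded random walks within ±drift_max_offset.  The reference receiver
    (and, more weakly, cabled units) stay at zero offset.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    interval = config.drift_knot_interval_s
    knots = np.arange(0.0, config.duration_s + interval, interval)
    spec = {}
    for _, r in array.iterrows():
        if r["role"] == REFERENCE_ROLE:
            spec[r["id"]] = [(float(k), 0.0) for k in knots]
            continue
        amp = config.drift_max_offset_s * (0.1 if r["role"] == "cabled" else 1.0)
        vals = [rng.uniform(-amp, amp)]
        for _ in knots[1:]:
            step = rng.normal(0, amp / 2.0)
            vals.append(float(np.clip(vals[-1] + step, -amp, amp)))
        spec[r["id"]] = [(float(k), float(v)) for k, v in zip(knots, vals)]
    return spec


def offset_function(drift_spec: dict):
    """Return f(receiver_id, times) -> true clock offsets (flat beyond ends)."""
    tables = {
        rid: (np.array([k for k, _ in kv]), np.array([v for _, v in kv]))
        for rid, kv in drift_spec.items()
    }

    def f(receiver_id, times):
        k, v = tables[receiver_id]
        return np.interp(np.asarray(times, float), k, v)

    return f


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

def simulate_detections(
    tracks: pd.DataFrame,
    array: pd.DataFrame,
    config: ScenarioConfig,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate raw receive times for beacon and tag transmissions.

    raw_time = emission + distance/c + clock_offset(receiver) + noise, with
    a ``corrupt_frac`` of detections given an extra positive delay (a
    surrogate for undetected multipath) and, if ``dup_frac`` > 0, extra
    duplicate rows (detected multipath echoes).  Returns the detection
    table and a truth record with emission positions/times, the drift
    spec, and corrupted/duplicate detection ids.
    """
    if config.sound_speed_ms <= 0:
        raise ValueError("sound speed must be positive")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    drift = config.drift_spec or random_drift_spec(config, array, rng)
    offs = offset_function(drift)
    c = config.sound_speed_ms

    em_t, em_x, em_y, em_z, em_src, em_kind = [], [], [], [], [], []
    # beacon emissions: each receiver doubles as a sync beacon
    for _, r in array.iterrows():
        phase = rng.uniform(0, config.beacon_interval_s)
        times = np.arange(phase, config.duration_s, config.beacon_interval_s)
        em_t.append(times)
        em_x.append(np.full(times.size, r["x"]))
        em_y.append(np.full(times.size, r["y"]))
        em_z.append(np.full(times.size, r["z"]))
        em_src.extend([r["id"]] * times.size)
        em_kind.extend(["beacon"] * times.size)
    # tag emissions along each track
    tag_z = -config.tag_depth_m
    if len(tracks):
        for tag, g in tracks.groupby("tag_id", sort=True):
            t0, t1 = g["t"].iloc[0], g["t"].iloc[-1]
            times = [t0 + rng.uniform(0, config.pri_s)]
            while times[-1] < t1:
                step = config.pri_s + rng.normal(0, config.pri_jitter_sd_s)
                times.append(times[-1] + max(step, 0.5 * config.pri_s))
            times = np.array(times[:-1]) if times[-1] >= t1 else np.array(times)
            if times.size == 0:
                continue
            em_t.append(times)
            em_x.append(np.interp(times, g["t"], g["x"]))
            em_y.append(np.interp(times, g["t"], g["y"]))
            em_z.append(np.full(times.size, tag_z))
            em_src.extend([tag] * times.size)
            em_kind.extend(["tag"] * times.size)

    em_t = np.concatenate(em_t)
    em_x = np.concatenate(em_x)
    em_y = np.concatenate(em_y)
    em_z = np.concatenate(em_z)
    em_src = np.array(em_src)
    em_kind = np.array(em_kind)
    n_em = em_t.size
    ping_id = np.arange(n_em)

    rx = array["x"].to_numpy()
    ry = array["y"].to_numpy()
    rz = array["z"].to_numpy()
    rid = array["id"].to_numpy()
    n_rx = len(array)

    # cross every emission with every receiver
    P = np.repeat(ping_id, n_rx)
    R = np.tile(np.arange(n_rx), n_em)
    d = np.sqrt(
        (em_x[P] - rx[R]) ** 2 + (em_y[P] - ry[R]) ** 2 + (em_z[P] - rz[R]) ** 2
    )
    detect = rng.random(P.size) < config.detection_prob
    P, R, d = P[detect], R[detect], d[detect]
    t_arr = em_t[P] + d / c
    offsets = np.empty(P.size)
    for i in range(n_rx):
        m = R == i
        offsets[m] = offs(rid[i], t_arr[m])
    noise = (
        rng.normal(0, config.arrival_noise_sd_s, P.size)
        if config.arrival_noise_sd_s > 0
        else 0.0
    )
    raw = t_arr + offsets + noise

    n_det = P.size
    corrupted = np.zeros(n_det, bool)
    if config.corrupt_frac > 0 and n_det:
        n_corrupt = int(round(config.corrupt_frac * n_det))
        idx = rng.choice(n_det, size=n_corrupt, replace=False)
        lo, hi = config.corrupt_delay_range_s
        raw = raw.copy()
        raw[idx] = raw[idx] + rng.uniform(lo, hi, n_corrupt)
        corrupted[idx] = True

    det = pd.DataFrame(
        {
            "det_id": np.arange(n_det),
            "receiver_id": rid[R],
            "source_id": em_src[P],
            "source_kind": em_kind[P],
            "raw_time_s": raw,
            "ping_id": P,
        }
    )
    duplicate = np.zeros(n_det, bool)
    if config.dup_frac > 0 and n_det:
        n_dup = int(round(config.dup_frac * n_det))
        idx = rng.choice(n_det, size=n_dup, replace=False)
        lo, hi = config.corrupt_delay_range_s
        dup = det.iloc[idx].copy()
        dup["raw_time_s"] = dup["raw_time_s"] + rng.uniform(lo, hi, n_dup)
        dup["det_id"] = n_det + np.arange(n_dup)
        det = pd.concat([det, dup], ignore_index=True)
        corrupted = np.concatenate([corrupted, np.zeros(n_dup, bool)])
        duplicate = np.concatenate([duplicate, np.ones(n_dup, bool)])

    det = det.sort_values(["receiver_id", "raw_time_s"], kind="stable").reset_index(
        drop=True
    )
    truth = {
        "emissions": pd.DataFrame(
            {
                "ping_id": ping_id,
                "source_id": em_src,
                "source_kind": em_kind,
                "t_emit": em_t,
                "x": em_x,
                "y": em_y,
                "z": em_z,
            }
        ),
        "drift_spec": drift,
        "corrupted_det_ids": np.flatnonzero(corrupted),
        "duplicate_det_ids": np.flatnonzero(duplicate),
    }
    return det, truth


# ---------------------------------------------------------------------------
# Gauges
# ---------------------------------------------------------------------------

def gen_gauges(field: VelocityField, config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Discharge, stage, and turbidity series consistent with the field.

    Q(t) is the cross-sectionally integrated flux of the gridded field at
    the upstream section; stage is the water-surface elevation there;
    turbidity is a seeded diel sinusoid with noise (NTU-like units).
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    ds = field.ds
    x0 = float(ds["x"].values[0])
    t = ds["t"].values
    y = ds["y"].values
    # full-depth average times depth = unit-width flux; integrate across y
    ubar, _ = field.velocity(
        np.full((t.size, y.size), x0),
        np.broadcast_to(y, (t.size, y.size)),
        np.broadcast_to(t[:, None], (t.size, y.size)),
        VerticalRange.FULL_DEPTH,
    )
    depth = field.depth(
        np.full((t.size, y.size), x0),
        np.broadcast_to(y, (t.size, y.size)),
        np.broadcast_to(t[:, None], (t.size, y.size)),
    )
    flux = np.where(np.isfinite(ubar) & np.isfinite(depth), ubar * depth, 0.0)
    Q = np.trapezoid(flux, y, axis=1)
    stage = ds["surface"].isel(x=0).mean("y").values
    turb = 10.0 + 3.0 * np.sin(2 * np.pi * t / 86400.0) + rng.normal(0, 0.5, t.size)
    return pd.DataFrame(
        {
            "t_s": t,
            "discharge_m3s": Q,
            "stage_m": stage,
            "turbidity": np.clip(turb, 0.1, None),
        }
    )


# ---------------------------------------------------------------------------
# Scenario bundle and file output
# ---------------------------------------------------------------------------

def generate_scenario(config: ScenarioConfig) -> dict:
    """Generate every pipeline input for one scenario.

    Returns dict with keys: array, field, tracks, detections, truth, gauges.
    """
    array = gen_array(config)
    fld = gen_field(config)
    tracks = simulate_fish(fld, config)
    detections, truth = simulate_detections(tracks, array, config)
    gauges = gen_gauges(fld, config)
    return {
        "array": array,
        "field": fld,
        "tracks": tracks,
        "detections": detections,
        "truth": truth,
        "gauges": gauges,
    }


def write_scenario(scn: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scn["array"].to_csv(out / "receivers.csv", index=False)
    scn["detections"].drop(columns=["ping_id"]).to_csv(
        out / "detections.csv", index=False
    )
    scn["field"].to_netcdf(out / "field.nc")
    scn["gauges"].to_csv(out / "gauges.csv", index=False)
    scn["tracks"].to_csv(out / "true_tracks.csv", index=False)
    scn["truth"]["emissions"].to_csv(out / "true_emissions.csv", index=False)
    drift_rows = [
        {"receiver_id": rid, "knot_time_s": k, "offset_s": v}
        for rid, kv in scn["truth"]["drift_spec"].items()
        for k, v in kv
    ]
    pd.DataFrame(drift_rows).to_csv(out / "true_clock_offsets.csv", index=False)
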