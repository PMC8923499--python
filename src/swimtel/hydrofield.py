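"""Gridded hydrodynamic fields: extraction, vorticity, skill metrics.

The central container is :class:`VelocityField`, a thin wrapper around an
:class:`xarray.Dataset` with dimensions ``(t, z, y, x)`` and variables
``u``/``v`` (horizontal water velocity, m/s), ``bed(y, x)`` and
``surface(t, y, x)`` (elevations, m, positive up).  All extraction is
vertically averaged over one of three slabs measured down from the
instantaneous water surface: the top 1 m, the top 2 m, or the full water
column — the three assumptions about where fish sit in the water column.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator


class VerticalRange(enum.Enum):
    """Vertical averaging slab, measured down from the water surface."""

    TOP_1M = "top1m"
    TOP_2M = "top2m"
    FULL_DEPTH = "full"

    @property
    def extent_m(self) -> float | None:
        """Slab thickness in meters; ``None`` means bed-to-surface."""
        return {"top1m": 1.0, "top2m": 2.0, "full": None}[self.value]

    @classmethod
    def parse(cls, s: "str | VerticalRange") -> "VerticalRange":
        if isinstance(s, cls):
            return s
        return cls(str(s).lower())


class DryPointError(ValueError):
    """Raised when a query point is dry or outside the grid."""

    def __init__(self, x, y, t):
        super().__init__(f"dry or out-of-grid point: x={x}, y={y}, t={t}")
        self.x, self.y, self.t = x, y, t


def _slab_average(values, z, z_lo, z_hi):
    """Average piecewise-linear-in-z ``values`` over [z_lo, z_hi] columns.

    values: array (..., nz) sampled at levels ``z`` (ascending).
    z_lo, z_hi: arrays broadcastable to values.shape[:-1].
    Exact trapezoid integration with partial end cells.
    """
    z = np.asarray(z, float)
    z_lo = np.asarray(z_lo, float)[..., None]
    z_hi = np.asarray(z_hi, float)[..., None]
    za, zb = z[:-1], z[1:]  # interval endpoints
    lo = np.maximum(z_lo, za)
    hi = np.minimum(z_hi, zb)
    overlap = np.clip(hi - lo, 0.0, None)
    mid = 0.5 * (lo + hi)
    frac = (mid - za) / (zb - za)
    v_mid = values[..., :-1] * (1 - frac) + values[..., 1:] * frac
    integral = np.sum(overlap * v_mid, axis=-1)
    thickness = np.squeeze(z_hi - z_lo, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = integral / thickness
    return np.where(thickness > 0, out, np.nan)


@dataclass
class VelocityField:
    """Gridded (t, z, y, x) horizontal velocity field with bed and surface."""

    ds: xr.Dataset
    _samplers: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for v in ("u", "v", "bed", "surface"):
            if v not in self.ds:
                raise ValueError(f"field dataset missing variable {v!r}")

    # -- coordinates ------------------------------------------------------
    @property
    def x(self):
        return self.ds["x"].values

    @property
    def y(self):
        return self.ds["y"].values

    @property
    def z(self):
        return self.ds["z"].values

    @property
    def t(self):
        return self.ds["t"].values

    # -- persistence ------------------------------------------------------
    def to_netcdf(self, path) -> None:
        self.ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "VelocityField":
        return cls(xr.load_dataset(path, engine="scipy"))

    # -- vertically averaged samplers -------------------------------------
    def _averaged(self, vrange: VerticalRange):
        """(t, y, x) slab-averaged u, v, plus depth and surface grids."""
        key = vrange.value
        if key not in self._samplers:
            u = self.ds["u"].transpose("t", "y", "x", "z").values
            v = self.ds["v"].transpose("t", "y", "x", "z").values
            bed = self.ds["bed"].transpose("y", "x").values
            surf = self.ds["surface"].transpose("t", "y", "x").values
            z_hi = surf
            if vrange.extent_m is None:
                z_lo = np.broadcast_to(bed, surf.shape)
            else:
                z_lo = np.maximum(surf - vrange.extent_m, bed)
            ubar = _slab_average(u, self.z, z_lo, z_hi)
            vbar = _slab_average(v, self.z, z_lo, z_hi)
            pts = (self.t, self.y, self.x)
            mk = lambda a: RegularGridInterpolator(
                pts, a, bounds_error=False, fill_value=np.nan
            )
            self._samplers[key] = (mk(ubar), mk(vbar))
        return self._samplers[key]

    def _surface_interp(self):
        if "surf" not in self._samplers:
            surf = self.ds["surface"].transpose("t", "y", "x").values
            self._samplers["surf"] = RegularGridInterpolator(
                (self.t, self.y, self.x), surf, bounds_error=False, fill_value=np.nan
            )
        if "bed" not in self._samplers:
            bed = self.ds["bed"].transpose("y", "x").values
            self._samplers["bed"] = RegularGridInterpolator(
                (self.y, self.x), bed, bounds_error=False, fill_value=np.nan
            )
        return self._samplers["surf"], self._samplers["bed"]

    def velocity(self, x, y, t, vrange: VerticalRange):
        """Slab-averaged velocity at points; vectorized.

        Returns (u, v) arrays shaped like the broadcast inputs; NaN where
        dry/out of grid.
        """
        vrange = VerticalRange.parse(vrange)
        x, y, t = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(t, float)
        )
        scalar = x.ndim == 0
        fu, fv = self._averaged(vrange)
        pts = np.stack([t, y, x], axis=-1)
        u, v = fu(pts), fv(pts)
        if scalar:
            return u.reshape(())[()], v.reshape(())[()]
        return u, v

    def depth(self, x, y, t):
        """Local water depth surface − bed (m); NaN if dry/out of grid."""
        x, y, t = np.broadcast_arrays(
            np.asarray(x, float), np.asarray(y, float), np.asarray(t, float)
        )
        scalar = x.ndim == 0
        fs, fb = self._surface_interp()
        d = fs(np.stack([t, y, x], axis=-1)) - fb(np.stack([y, x], axis=-1))
        d = np.where(d > 0, d, np.nan)
        return d.reshape(())[()] if scalar else d


def extract_velocity(field: VelocityField, x, y, t, vrange) -> np.ndarray:
    """Vertically averaged water velocity vector (u, v) at a point.

    Scalar inputs give a length-2 array; a dry or out-of-grid point raises
    :class:`DryPointError`.
    """
    u, v = field.velocity(x, y, t, vrange)
    if np.ndim(u) == 0:
        if not (np.isfinite(u) and np.isfinite(v)):
            raise DryPointError(x, y, t)
        return np.array([float(u), float(v)])
    return np.stack([u, v], axis=-1)


def local_depth(field: VelocityField, x, y, t) -> float:
    """Water depth surface(x,y,t) − bed(x,y) in meters."""
    d = field.depth(x, y, t)
    if np.ndim(d) == 0:
        if not np.isfinite(d):
            raise DryPointError(x, y, t)
        return float(d)
    return d


def vorticity(field: VelocityField, x, y, t, vrange, h: float = 2.0):
    """Vertical vorticity ω_xy = ∂v/∂x − ∂u/∂y by central differences.

    Each stencil sample is the slab-averaged velocity for ``vrange``.  The
    default spacing ``h`` = 2 m matches a typical lateral grid scale.  Any
    dry stencil point yields NaN (scalar input: raises).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    _, v_xp = field.velocity(x + h, y, t, vrange)
    _, v_xm = field.velocity(x - h, y, t, vrange)
    u_yp, _ = field.velocity(x, y + h, t, vrange)
    u_ym, _ = field.velocity(x, y - h, t, vrange)
    om = (v_xp - v_xm) / (2 * h) - (u_yp - u_ym) / (2 * h)
    if np.ndim(om) == 0:
        if not np.isfinite(om):
            raise DryPointError(x, y, t)
        return float(om)
    return om


# ---------------------------------------------------------------------------
# Hydrodynamic skill metrics (bias, uRMSE, target-diagram coordinates)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    bias: np.ndarray            # (bu, bv), m/s
    urmse_total: float          # m/s
    urmse_u: float
    urmse_v: float
    target_x: float             # signed uRMSE (variance under/over-prediction)
    target_y: float             # longitudinal bias

    def to_dict(self) -> dict:
        return {
            "bias_u": float(self.bias[0]),
            "bias_v": float(self.bias[1]),
            "urmse_total": self.urmse_total,
            "urmse_u": self.urmse_u,
            "urmse_v": self.urmse_v,
            "target_x": self.target_x,
            "target_y": self.target_y,
        }


def calibration_metrics(modeled, observed) -> CalibrationResult:
    """Velocity bias vector and unbiased RMSE over paired samples.

    bias b = <m_i − o_i> componentwise; uRMSE = sqrt(<‖m_i − o_i − b‖²>),
    with componentwise analogues.  The target-diagram abscissa is the total
    uRMSE signed by whether the modeled speeds have more or less variance
    than the observed speeds; the ordinate is the longitudinal bias.
    """
    m = np.atleast_2d(np.asarray(modeled, float))
    o = np.atleast_2d(np.asarray(observed, float))
    if m.shape != o.shape or m.shape[0] < 2 or m.shape[1] != 2:
        raise ValueError("need >= 2 paired 2-D velocity vectors")
    d = m - o
    b = d.mean(axis=0)
    dd = d - b
    urmse_tot = float(np.sqrt(np.mean(np.sum(dd**2, axis=1))))
    urmse_u = float(np.sqrt(np.mean(dd[:, 0] ** 2)))
    urmse_v = float(np.sqrt(np.mean(dd[:, 1] ** 2)))
    sign = np.sign(
        np.std(np.linalg.norm(m, axis=1)) - np.std(np.linalg.norm(o, axis=1))
    )
    if sign == 0:
        sign = 1.0
    return CalibrationResult(
        bias=b,
        urmse_total=urmse_tot,
        urmse_u=urmse_u,
        urmse_v=urmse_v,
        target_x=float(sign * urmse_tot),
        target_y=float(b[0]),
    )


# ---------------------------------------------------------------------------
# Mean river velocity u_river = Q · L_a / V(stage)
# ---------------------------------------------------------------------------

@dataclass
class RiverReach:
    """Reach-scale advection: discharge, stage, and a stage→volume curve.

    ``u_river(t) = Q(t) · L_a / V(stage(t))`` where L_a is the
    characteristic along-flow length of the analysis region (default
    234 m) and V the wetted volume of the region at the current stage.
    """

    times: np.ndarray            # s
    discharge: np.ndarray        # m^3/s, Q(t)
    stage: np.ndarray            # m
    volume_stages: np.ndarray    # m, ascending
    volume_values: np.ndarray    # m^3, V at each stage
    L_a: float = 234.0
    turbidity: np.ndarray | None = None  # optional, same times

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.discharge = np.asarray(self.discharge, float)
        self.stage = np.asarray(self.stage, float)
        self.volume_stages = np.asarray(self.volume_stages, float)
        self.volume_values = np.asarray(self.volume_values, float)
        if self.L_a <= 0:
            raise ValueError("L_a must be positive")
        if np.any(np.diff(self.volume_stages) <= 0):
            raise ValueError("volume curve stages must be strictly increasing")
        if np.any(self.volume_values <= 0):
            raise ValueError("volumes must be positive")

    @classmethod
    def from_frames(cls, gauges: pd.DataFrame, volume_curve: pd.DataFrame,
                    L_a: float = 234.0) -> "RiverReach":
        """gauges: columns t_s, discharge_m3s, stage_m[, turbidity].
        volume_curve: columns stage_m, volume_m3."""
        turb = gauges["turbidity"].to_numpy() if "turbidity" in gauges else None
        return cls(
            times=gauges["t_s"].to_numpy(),
            discharge=gauges["discharge_m3s"].to_numpy(),
            stage=gauges["stage_m"].to_numpy(),
            volume_stages=volume_curve["stage_m"].to_numpy(),
            volume_values=volume_curve["volume_m3"].to_numpy(),
            L_a=L_a,
            turbidity=turb,
        )

    def volume(self, stage):
        stage = np.asarray(stage, float)
        lo, hi = self.volume_stages[0], self.volume_stages[-1]
        if np.any(stage < lo) or np.any(stage > hi):
            raise ValueError("stage outside volume-curve domain")
        return np.interp(stage, self.volume_stages, self.volume_values)


def mean_river_velocity(reach: RiverReach, t) -> np.ndarray | float:
    """Reach-average downstream water speed u_river(t) = Q·L_a/V (m/s)."""
    t = np.asarray(t, float)
    if np.any(t < reach.times[0]) or np.any(t > reach.times[-1]):
        raise ValueError("t outside gauge series coverage")
    Q = np.interp(t, reach.times, reach.discharge)
    stage = np.interp(t, reach.times, reach.stage)
    u = Q * reach.L_a / reach.volume(stage)
    return float(u) if np.ndim(u) == 0 else u


def write_metrics_json(result: CalibrationResult, path) -> None:
    with open(path, "w") as f:
        json.dump(result.to_dict(), f, indent=2)
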