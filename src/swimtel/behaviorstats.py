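"""Weighted behavioral summaries and supporting statistics.

Swim-velocity records are weighted by the inverse of each individual's
segment count (so every fish counts equally regardless of how long it
lingered in the array), with an extra 1/3 when the three vertical-range
variants are pooled as replicate measurements.  Summaries are weighted
medians with bootstrap 5–95% confidence intervals, weighted kernel
density estimates, the weighted occurrence of positive rheotaxis, a
stride-based sensitivity of speed estimates to uncorrelated position
noise, and a paired comparison of per-fish ground velocity against the
mean river velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hydrofield import VelocityField
from .swimvec import make_segments, swim_records


def segment_weights(records: pd.DataFrame, pool_vranges: bool = False) -> pd.DataFrame:
    """weight = 1 / n_segments(tag) [× 1/3 when vertical ranges are pooled].

    n_segments counts unique segments per tag (each segment contributes one
    row per vertical range).  Per-tag summed weight is 1 either way.
    """
    rec = records.copy()
    nseg = rec.groupby(["tag_id", "vrange"])["t0"].transform("size")
    rec["weight"] = 1.0 / nseg
    if pool_vranges:
        rec["weight"] /= rec.groupby("tag_id")["vrange"].transform("nunique")
    return rec


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative normalized weight reaches 0.5."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("need nonempty values with positive total weight")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order]) / w.sum()
    return float(v[order][np.searchsorted(cw, 0.5)])


def weighted_median_ci(
    values, weights, n_boot: int = 1000, seed: int = 0, ci=(5.0, 95.0)
) -> tuple[float, tuple[float, float]]:
    """Weighted median with bootstrap percentile CI of the median.

    Resamples n values with replacement, probability ∝ weight, per
    replicate; the CI is the 5th/95th percentile of replicate medians.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    med = weighted_median(v, w)
    rng = np.random.default_rng(seed)
    p = w / w.sum()
    n = v.size
    meds = np.empty(n_boot)
    idx = rng.choice(n, size=(n_boot, n), replace=True, p=p)
    sample = v[idx]
    sample.sort(axis=1)
    meds = sample[:, (n - 1) // 2] if n % 2 else 0.5 * (
        sample[:, n // 2 - 1] + sample[:, n // 2]
    )
    lo, hi = np.percentile(meds, ci)
    return med, (float(lo), float(hi))


def weighted_sd(values, weights) -> float:
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    mean = np.average(v, weights=w)
    return float(np.sqrt(np.average((v - mean) ** 2, weights=w)))


def silverman_bandwidth(values, weights) -> float:
    """Silverman's rule on the weighted sd and effective sample size."""
    w = np.asarray(weights, float)
    neff = w.sum() ** 2 / np.sum(w**2)
    sd = weighted_sd(values, w)
    if sd == 0:
        raise ValueError("zero spread; bandwidth undefined")
    return float(1.06 * sd * neff ** (-1 / 5))


def weighted_kde(
    values, weights, bandwidth: float | None = None, n_grid: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel weighted density on a regular grid.

    The grid spans the data ± 3 bandwidths; weights are normalized so the
    density integrates to 1.  Bandwidth defaults to Silverman's rule on
    the weighted standard deviation.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if bandwidth is None:
        if np.unique(v).size < 2:
            raise ValueError("need at least 2 distinct values for a rule-based bandwidth")
        bandwidth = silverman_bandwidth(v, w)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(v.min() - 3 * bandwidth, v.max() + 3 * bandwidth, n_grid)
    wn = w / w.sum()
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = (wn[None, :] * np.exp(-0.5 * z**2)).sum(axis=1) / (
        bandwidth * np.sqrt(2 * np.pi)
    )
    return grid, dens


def rheotaxis_fraction(records: pd.DataFrame, weighted: bool = True) -> float:
    """Weighted fraction of records swimming against the flow (u_long < 0)."""
    u = records["u_long"].to_numpy(float)
    ok = np.isfinite(u)
    w = records["weight"].to_numpy(float) if weighted else np.ones(u.size)
    u, w = u[ok], w[ok]
    if w.sum() <= 0:
        raise ValueError("no finite u_long records")
    return float(w[u < 0].sum() / w.sum())


@dataclass
class SummaryStats:
    vrange: str
    median: float
    ci_5_95: tuple
    rheotaxis_fraction: float
    rheotaxis_fraction_unweighted: float
    n_individuals: int
    n_records: int


def summarize_records(
    records: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> list[SummaryStats]:
    """Per-vertical-range weighted summary of longitudinal swimming."""
    out = []
    for vr, g in records.groupby("vrange", sort=True):
        g = g[np.isfinite(g["u_long"])]
        med, ci = weighted_median_ci(
            g["u_long"], g["weight"], n_boot=n_boot, seed=seed
        )
        out.append(
            SummaryStats(
                vrange=vr,
                median=med,
                ci_5_95=ci,
                rheotaxis_fraction=rheotaxis_fraction(g),
                rheotaxis_fraction_unweighted=rheotaxis_fraction(g, weighted=False),
                n_individuals=g["tag_id"].nunique(),
                n_records=len(g),
            )
        )
    return out


def stride_speeds(
    track: pd.DataFrame,
    field: VelocityField,
    vrange: str = "top2m",
    stride: int = 1,
) -> np.ndarray:
    """Swim speeds from fix pairs (i, i+stride) along one track.

    Larger strides average out uncorrelated position noise: comparing the
    stride-1 and stride-k speed distributions isolates the positive bias
    that noise adds to speed (not velocity) estimates.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    track = track.sort_values("t", kind="stable")
    if len(track) <= stride:
        return np.array([])
    sub_records = []
    for phase in range(stride):
        sub = track.iloc[phase::stride]
        if len(sub) < 2:
            continue
        seg = make_segments(sub, max_gap=np.inf)
        if seg.empty:
            continue
        rec = swim_records(seg, field, vranges=(vrange,))
        if not rec.empty:
            sub_records.append(np.hypot(rec["us_u"], rec["us_v"]))
    return np.concatenate(sub_records) if sub_records else np.array([])


@dataclass
class PairedComparison:
    pairs: pd.DataFrame          # tag_id, u_ground, u_river
    mean_difference: float
    t_statistic: float
    p_value: float
    ci_90: tuple
    n: int
    degenerate: bool = False


def ground_vs_river(segments_by_tag: pd.DataFrame, reach) -> PairedComparison:
    """Paired t-test of downstream ground velocity vs mean river velocity.

    Per fish: the x-component of velocity over ground averaged over its
    in-region segments, paired with u_river time-averaged over the same
    interval.  Two-sided paired t with df N−1 and a 90% CI of the mean
    difference.
    """
    from .hydrofield import mean_river_velocity

    rows = []
    for tag, g in segments_by_tag.groupby("tag_id", sort=True):
        t0, t1 = g["t0"].min(), g["t1"].max()
        tt = np.linspace(t0, t1, max(2, int((t1 - t0) / 60) + 2))
        rows.append(
            {
                "tag_id": tag,
                "u_ground": float(np.average(g["uog_u"], weights=g["t1"] - g["t0"])),
                "u_river": float(np.mean(mean_river_velocity(reach, tt))),
            }
        )
    pairs = pd.DataFrame(rows)
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 fish for the paired comparison")
    d = pairs["u_ground"].to_numpy() - pairs["u_river"].to_numpy()
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        return PairedComparison(
            pairs=pairs,
            mean_difference=mean_d,
            t_statistic=np.nan,
            p_value=1.0 if mean_d == 0 else 0.0,
            ci_90=(mean_d, mean_d),
            n=n,
            degenerate=True,
        )
    se = sd_d / np.sqrt(n)
    tstat = mean_d / se
    p = 2 * stats.t.sf(abs(tstat), df=n - 1)
    tcrit = stats.t.ppf(0.95, df=n - 1)
    return PairedComparison(
        pairs=pairs,
        mean_difference=mean_d,
        t_statistic=float(tstat),
        p_value=float(p),
        ci_90=(mean_d - tcrit * se, mean_d + tcrit * se),
        n=n,
    )


def classify_behavior(
    track_records: pd.DataFrame,
    tau: float = 0.05,
    tau_lat: float = 0.05,
    min_records: int = 5,
) -> str | None:
    """Heuristic track label from median flow-frame swim components.

    median u_long < −tau → positive_rheotaxis; > tau → negative_rheotaxis;
    else median |v_lat| > tau_lat → lateral; else passive.  Tracks with
    fewer than ``min_records`` records are unlabeled (None).
    """
    g = track_records[np.isfinite(track_records["u_long"])]
    if len(g) < min_records:
        return None
    med_long = float(np.median(g["u_long"]))
    med_lat = float(np.median(np.abs(g["v_lat"])))
    if med_long < -tau:
        return "positive_rheotaxis"
    if med_long > tau:
        return "negative_rheotaxis"
    if med_lat > tau_lat:
        return "lateral"
    return "passive"


def bl_normalize(speed_ms, fork_length_mm) -> float | np.ndarray:
    """Speed in body (fork) lengths per second: v / (FL/1000)."""
    fl = np.asarray(fork_length_mm, float)
    if np.any(fl <= 0):
        raise ValueError("fork length must be positive")
    out = np.asarray(speed_ms, float) / (fl / 1000.0)
    return float(out) if np.ndim(out) == 0 else out


GAM_COLUMNS = [
    "tag_id", "vrange", "mid_t", "u_long", "abs_v_lat", "speed_hydro",
    "vorticity", "depth", "time_of_day_h", "u_river", "turbidity", "weight",
]


def export_gam_table(records: pd.DataFrame) -> pd.DataFrame:
    """Covariate table for external smooth-model (GAM) fitting.

    One row per (segment, vertical range), weights including the pooled
    1/3 factor; fitting itself is out of scope here.
    """
    rec = segment_weights(records, pool_vranges=True)
    rec["abs_v_lat"] = np.abs(rec["v_lat"])
    missing = [c for c in GAM_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"records missing covariates: {missing}")
    return rec[GAM_COLUMNS].reset_index(drop=True)
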