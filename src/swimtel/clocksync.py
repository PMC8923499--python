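"""Receiver clock synchronization from beacon-to-beacon detections.

Each receiver's clock offset is modeled as a continuous piecewise-linear
function on a shared regular knot grid.  With receiver positions known,
each beacon detection gives one linear equation

    raw_time − distance(beacon, receiver)/c  =  T_k + Σ_j w_j(t)·θ_{r,j}

in the unknown per-ping emission times T_k and the offset knot values θ.
One receiver is the gauge-fixing reference with θ ≡ 0.  The emission times
are eliminated exactly by within-ping centering (profiling), leaving a
small sparse normal system in θ alone.  Erroneous detections (multipath,
noise bursts) are flagged by iteratively removing the detection with the
largest absolute residual and re-solving: the iteration continues while
the RMS residual exceeds ``rms_threshold`` (1 ms, the field rule) or the
worst residual exceeds an outlier cutoff (default 3× the RMS threshold),
so that isolated gross outliers are flagged even when they are too sparse
to lift the overall RMS above threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Clock model
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """Per-receiver continuous piecewise-linear clock offsets (seconds)."""

    knots: np.ndarray                  # shared, strictly increasing
    offsets: dict                      # receiver_id -> array over knots
    reference_id: str

    def __post_init__(self):
        self.knots = np.asarray(self.knots, float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def offset(self, receiver_id: str, times) -> np.ndarray:
        """Offset at ``times``; linear between knots, flat beyond the ends."""
        if receiver_id not in self.offsets:
            raise KeyError(f"unknown receiver {receiver_id!r}")
        return np.interp(np.asarray(times, float), self.knots, self.offsets[receiver_id])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"receiver_id": rid, "knot_time_s": k, "offset_s": v}
            for rid, vals in self.offsets.items()
            for k, v in zip(self.knots, vals)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_id: str) -> "ClockModel":
        knots = np.unique(df["knot_time_s"].to_numpy())
        offsets = {
            rid: g.sort_values("knot_time_s")["offset_s"].to_numpy()
            for rid, g in df.groupby("receiver_id")
        }
        return cls(knots=knots, offsets=offsets, reference_id=reference_id)


@dataclass
class SyncSolution:
    model: ClockModel
    removed: pd.DataFrame            # det_id, residual_s
    rms_residual: float              # s, over retained detections
    n_iterations: int
    success: bool
    window: tuple
    unsolvable_receivers: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Linear system assembly
# ---------------------------------------------------------------------------

def _cluster_pings(times: np.ndarray, gap: float) -> np.ndarray:
    """Group sorted times into transmission events split at gaps > ``gap``."""
    groups = np.zeros(times.size, dtype=np.int64)
    if times.size:
        groups[1:] = np.cumsum(np.diff(times) > gap)
    return groups


@dataclass
class SyncSystem:
    """Centered sparse least-squares system for the offset knot values."""

    det_id: np.ndarray
    ping: np.ndarray                 # 0..n_pings-1
    rec: np.ndarray                  # receiver index in receivers list
    col0: np.ndarray                 # first knot column (-1 for reference)
    col1: np.ndarray
    w0: np.ndarray
    w1: np.ndarray
    y: np.ndarray                    # raw − distance/c
    knots: np.ndarray
    receivers: list                  # all receiver ids, order defines rec
    ref_id: str
    n_pings: int
    unsolvable: list

    @property
    def n_equations(self) -> int:
        return self.y.size

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def n_params(self) -> int:
        """Offset unknowns θ (reference excluded)."""
        return (len(self.receivers) - 1) * self.n_knots

    @property
    def n_unknowns(self) -> int:
        """Total unknowns: per-ping emission times plus offset knots."""
        return self.n_pings + self.n_params


def build_sync_system(
    detections: pd.DataFrame,
    array: pd.DataFrame,
    knot_interval: float,
    window: tuple | None = None,
    sound_speed: float = 1470.0,
    ping_gap_s: float = 2.0,
) -> SyncSystem:
    """Assemble the centered linear system from beacon detections.

    Beacon detections are clustered into transmission events per source by
    splitting the time-sorted raw times at gaps larger than ``ping_gap_s``
    (which must exceed the maximum propagation delay plus clock-offset
    spread, and be well under the beacon interval).
    """
    det = detections[detections["source_kind"] == "beacon"]
    if window is not None:
        t0, t1 = window
        det = det[(det["raw_time_s"] >= t0) & (det["raw_time_s"] < t1)]
    else:
        if det.empty:
            raise ValueError("no beacon detections in window")
        t0 = float(det["raw_time_s"].min())
        t1 = float(det["raw_time_s"].max()) + 1e-9
    if det.empty:
        raise ValueError("no beacon detections in window")

    ids = array["id"].tolist()
    ref_candidates = array[array["role"] == "reference"]["id"].tolist()
    if len(ref_candidates) != 1:
        raise ValueError("array must contain exactly one reference receiver")
    ref_id = ref_candidates[0]
    pos = {r["id"]: np.array([r["x"], r["y"], r["z"]]) for _, r in array.iterrows()}
    unknown = set(det["receiver_id"]) - set(ids)
    if unknown:
        raise ValueError(f"detections from receivers not in array: {sorted(unknown)}")

    # cluster per beacon source into pings
    det = det.sort_values(["source_id", "raw_time_s"], kind="stable")
    ping_global = np.empty(len(det), dtype=np.int64)
    base = 0
    for src, g in det.groupby("source_id", sort=True):
        grp = _cluster_pings(g["raw_time_s"].to_numpy(), ping_gap_s)
        ping_global[det.index.get_indexer(g.index)] = grp + base
        base += grp[-1] + 1 if grp.size else 0
    det = det.assign(_ping=ping_global)
    # within a ping keep at most one detection per receiver (earliest)
    det = det.sort_values("raw_time_s", kind="stable").drop_duplicates(
        ["_ping", "receiver_id"], keep="first"
    )
    # re-densify ping ids
    _, ping = np.unique(det["_ping"].to_numpy(), return_inverse=True)
    n_pings = int(ping.max()) + 1 if ping.size else 0

    # knot grid covering the window
    n_int = max(1, int(np.ceil((t1 - t0) / knot_interval)))
    knots = t0 + knot_interval * np.arange(n_int + 1)
    K = knots.size

    rec_index = {rid: i for i, rid in enumerate(ids)}
    rec = det["receiver_id"].map(rec_index).to_numpy()
    src_xyz = np.stack([pos[s] for s in det["source_id"]], axis=0)
    rec_xyz = np.stack([pos[r] for r in det["receiver_id"]], axis=0)
    d = np.linalg.norm(src_xyz - rec_xyz, axis=1)
    raw = det["raw_time_s"].to_numpy()
    y = raw - d / sound_speed

    # piecewise-linear weights at the raw times
    j = np.clip(np.searchsorted(knots, raw, side="right") - 1, 0, K - 2)
    w1 = (raw - knots[j]) / (knots[j + 1] - knots[j])
    w0 = 1.0 - w1

    # θ columns: (receiver order excluding reference) × knots
    theta_ids = [r for r in ids if r != ref_id]
    theta_index = {rid: i for i, rid in enumerate(theta_ids)}
    is_ref = det["receiver_id"].to_numpy() == ref_id
    tcol = np.array(
        [theta_index.get(r, -1) for r in det["receiver_id"]], dtype=np.int64
    )
    col0 = np.where(is_ref, -1, tcol * K + j)
    col1 = np.where(is_ref, -1, tcol * K + j + 1)

    # connectivity: a receiver is solvable iff linked to the reference
    # through shared pings (union-find over receivers)
    parent = {r: r for r in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for _, g in det.groupby("_ping"):
        rs = g["receiver_id"].tolist()
        for r in rs[1:]:
            parent[find(r)] = find(rs[0])
    heard = set(det["receiver_id"])
    root_ref = find(ref_id)
    unsolvable = [
        r for r in ids if r != ref_id and (r not in heard or find(r) != root_ref)
    ]

    return SyncSystem(
        det_id=det["det_id"].to_numpy(),
        ping=ping,
        rec=rec,
        col0=col0,
        col1=col1,
        w0=np.where(is_ref, 0.0, w0),
        w1=np.where(is_ref, 0.0, w1),
        y=y,
        knots=knots,
        receivers=ids,
        ref_id=ref_id,
        n_pings=n_pings,
        unsolvable=unsolvable,
    )


# ---------------------------------------------------------------------------
# Iterative solver
# ---------------------------------------------------------------------------

def _normal_system(sys: SyncSystem, active: np.ndarray):
    """Dense normal matrix and rhs of the ping-centered system."""
    P = sys.n_params
    idx = np.flatnonzero(active)
    rows = np.concatenate([idx, idx])
    cols = np.concatenate([sys.col0[idx], sys.col1[idx]])
    data = np.concatenate([sys.w0[idx], sys.w1[idx]])
    keep = cols >= 0
    G = sparse.csr_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(sys.y.size, P)
    )
    ping = sys.ping
    M = sparse.csr_matrix(
        (np.ones(idx.size), (idx, ping[idx])), shape=(sys.y.size, sys.n_pings)
    )
    m = np.bincount(ping[idx], minlength=sys.n_pings).astype(float)
    inv_m = np.divide(1.0, m, out=np.zeros_like(m), where=m > 0)
    B = (M.T @ G).tocsr()                      # n_pings × P group sums
    Dinv = sparse.diags(inv_m)
    N = (G.T @ G - B.T @ Dinv @ B).toarray()
    ysum = M.T @ (sys.y * active)
    rhs = G.T @ (sys.y * active) - B.T @ (inv_m * ysum)
    return N, rhs, G


def _residuals(sys: SyncSystem, theta: np.ndarray, active: np.ndarray):
    """Ping-centered residuals; zero for inactive rows."""
    pred = np.zeros(sys.y.size)
    m0 = active & (sys.col0 >= 0)
    pred[m0] = sys.w0[m0] * theta[sys.col0[m0]] + sys.w1[m0] * theta[sys.col1[m0]]
    v = np.where(active, sys.y - pred, 0.0)
    cnt = np.bincount(sys.ping[active], minlength=sys.n_pings).astype(float)
    s = np.bincount(sys.ping[active], weights=v[active], minlength=sys.n_pings)
    mean = np.divide(s, cnt, out=np.zeros_like(s), where=cnt > 0)
    r = np.where(active, v - mean[sys.ping], 0.0)
    # singleton pings carry no information once centered
    r[active & (cnt[sys.ping] < 2)] = 0.0
    return r


def _group_update(N, rhs, sys, members_active, removed_i):
    """Downdate N, rhs for removal of detection ``removed_i`` from its ping."""
    def accum(idx_list):
        cols, vals, ssum = [], [], 0.0
        for i in idx_list:
            if sys.col0[i] >= 0:
                cols.extend((sys.col0[i], sys.col1[i]))
                vals.extend((sys.w0[i], sys.w1[i]))
            ssum += sys.y[i]
        if cols:
            cols = np.asarray(cols)
            vals = np.asarray(vals, float)
            uc, inv = np.unique(cols, return_inverse=True)
            uv = np.zeros(uc.size)
            np.add.at(uv, inv, vals)
        else:
            uc, uv = np.array([], dtype=int), np.array([])
        return uc, uv, ssum

    old = members_active
    new = [i for i in old if i != removed_i]
    uc_o, uv_o, s_o = accum(old)
    uc_n, uv_n, s_n = accum(new)
    m_o, m_n = len(old), len(new)
    i = removed_i
    # subtract g_i g_iᵀ and g_i y_i
    if sys.col0[i] >= 0:
        ci = np.array([sys.col0[i], sys.col1[i]])
        wi = np.array([sys.w0[i], sys.w1[i]])
        N[np.ix_(ci, ci)] -= np.outer(wi, wi)
        rhs[ci] -= wi * sys.y[i]
    # re-center: + b_o b_oᵀ/m_o − b_n b_nᵀ/m_n (and for rhs with s)
    if m_o > 0 and uc_o.size:
        N[np.ix_(uc_o, uc_o)] += np.outer(uv_o, uv_o) / m_o
        rhs[uc_o] += uv_o * (s_o / m_o)
    if m_n > 0 and uc_n.size:
        N[np.ix_(uc_n, uc_n)] -= np.outer(uv_n, uv_n) / m_n
        rhs[uc_n] -= uv_n * (s_n / m_n)


def _solve_theta(N, rhs):
    theta, *_ = np.linalg.lstsq(N, rhs, rcond=None)
    return theta


def solve_window(
    sys: SyncSystem,
    rms_threshold: float = 1e-3,
    resid_threshold: float | None = None,
    removal_cap: int | None = None,
) -> SyncSolution:
    """Iterative sparse least squares with worst-residual removal."""
    n = sys.n_equations
    if resid_threshold is None:
        resid_threshold = 3.0 * rms_threshold
    if removal_cap is None:
        removal_cap = max(int(0.005 * n), 100)

    active = np.ones(n, bool)
    members = [[] for _ in range(sys.n_pings)]
    for i, p in enumerate(sys.ping):
        members[p].append(i)

    N, rhs, _ = _normal_system(sys, active)
    if np.any(np.diag(N) <= 1e-12):
        bad_cols = np.flatnonzero(np.diag(N) <= 1e-12)
        K = sys.n_knots
        theta_ids = [r for r in sys.receivers if r != sys.ref_id]
        bad_recv = sorted({theta_ids[c // K] for c in bad_cols})
        log.warning("rank-deficient sync system; unconstrained knots for %s", bad_recv)

    theta = _solve_theta(N, rhs)
    r = _residuals(sys, theta, active)
    removed_ids, removed_res = [], []
    it = 0
    success = True
    while True:
        na = int(active.sum())
        rms = float(np.sqrt(np.sum(r**2) / na)) if na else 0.0
        worst = int(np.argmax(np.abs(r)))
        worst_val = abs(r[worst])
        if rms <= rms_threshold and worst_val <= resid_threshold:
            break
        if len(removed_ids) >= removal_cap:
            log.warning("sync removal cap (%d) reached; flagging window", removal_cap)
            success = False
            break
        removed_ids.append(int(sys.det_id[worst]))
        removed_res.append(float(r[worst]))
        _group_update(N, rhs, sys, [i for i in members[sys.ping[worst]] if active[i]], worst)
        active[worst] = False
        theta = _solve_theta(N, rhs)
        r = _residuals(sys, theta, active)
        it += 1

    K = sys.n_knots
    offsets = {sys.ref_id: np.zeros(K)}
    for i, rid in enumerate(r_ for r_ in sys.receivers if r_ != sys.ref_id):
        offsets[rid] = theta[i * K : (i + 1) * K].copy()
    model = ClockModel(knots=sys.knots, offsets=offsets, reference_id=sys.ref_id)
    na = int(active.sum())
    rms = float(np.sqrt(np.sum(r**2) / na)) if na else 0.0
    return SyncSolution(
        model=model,
        removed=pd.DataFrame({"det_id": removed_ids, "residual_s": removed_res}),
        rms_residual=rms,
        n_iterations=it,
        success=success and not sys.unsolvable,
        window=(float(sys.knots[0]), float(sys.knots[-1])),
        unsolvable_receivers=list(sys.unsolvable),
    )


def solve_sync(
    detections: pd.DataFrame,
    array: pd.DataFrame,
    knot_interval: float = 3600.0,
    rms_threshold: float = 1e-3,
    window_len_s: float = 5 * 86400.0,
    sound_speed: float = 1470.0,
    resid_threshold: float | None = None,
    removal_cap: int | None = None,
) -> list[SyncSolution]:
    """Solve clock offsets in consecutive windows (default five-day).

    Returns one :class:`SyncSolution` per window.
    """
    beacons = detections[detections["source_kind"] == "beacon"]
    if beacons.empty:
        raise ValueError("no beacon detections")
    t0 = float(beacons["raw_time_s"].min())
    t1 = float(beacons["raw_time_s"].max()) + 1e-9
    sols = []
    w0 = t0
    while w0 < t1:
        w1 = min(w0 + window_len_s, t1)
        sys = build_sync_system(
            detections, array, knot_interval, window=(w0, w1), sound_speed=sound_speed
        )
        sols.append(
            solve_window(
                sys,
                rms_threshold=rms_threshold,
                resid_threshold=resid_threshold,
                removal_cap=removal_cap,
            )
        )
        w0 = w1
    return sols


def merge_models(solutions: list[SyncSolution]) -> ClockModel:
    """Concatenate per-window models into one piecewise-linear model."""
    if len(solutions) == 1:
        return solutions[0].model
    knots = []
    offsets: dict[str, list] = {}
    for sol in sorted(solutions, key=lambda s: s.window[0]):
        m = sol.model
        sel = (
            np.ones(m.knots.size, bool)
            if not knots
            else m.knots > knots[-1] + 1e-9
        )
        knots.extend(m.knots[sel])
        for rid, vals in m.offsets.items():
            offsets.setdefault(rid, []).extend(np.asarray(vals)[sel])
    return ClockModel(
        knots=np.array(knots),
        offsets={k: np.array(v) for k, v in offsets.items()},
        reference_id=solutions[0].model.reference_id,
    )


def apply_sync(detections: pd.DataFrame, model: ClockModel) -> pd.DataFrame:
    """Correct raw receive times: corrected = raw − offset(receiver, raw).

    Rows from receivers absent from the model are dropped (logged).
    """
    det = detections.copy()
    known = det["receiver_id"].isin(model.offsets.keys())
    if not known.all():
        log.warning("dropping %d detections from unknown receivers", (~known).sum())
        det = det[known].copy()
    corrected = det["raw_time_s"].to_numpy(float).copy()
    for rid, g in det.groupby("receiver_id"):
        ix = det.index.get_indexer(g.index)
        corrected[ix] = g["raw_time_s"].to_numpy() - model.offset(
            rid, g["raw_time_s"].to_numpy()
        )
    det["corrected_time_s"] = corrected
    return det
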