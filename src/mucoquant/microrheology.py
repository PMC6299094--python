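"""Passive microbead rheology: detection, linking, drift correction and MSD.

The central quantity is the per-bead mean squared displacement computed with
overlapping windows,

    msd(tau) = 1/(N - tau) * sum_{i=1}^{N-tau} (x_{i+tau} - x_i)^2 + (y_{i+tau} - y_i)^2,

with ``N`` the number of frames and ``tau`` an integer frame lag.  Ensemble
curves average per-bead curves with equal weight; drift is removed globally
by a least-squares line on the ensemble-mean position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .stats_utils import holm_sidak

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "MSDCurve",
    "detect_and_link",
    "correct_linear_drift",
    "compute_msd",
    "ensemble_msd",
    "fit_scaling",
    "msd_dose_response",
]


@dataclass
class Trajectory:
    """Time-ordered 2-D positions of a single bead, in micrometres."""

    bead_id: int
    times: np.ndarray  # seconds, uniformly spaced
    x: np.ndarray  # um
    y: np.ndarray  # um

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("times, x, y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("positions must be finite")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ValueError("times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing one acquisition."""

    trajectories: list[Trajectory]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for tr in self.trajectories:
            for i in range(tr.n_frames):
                rows.append((tr.bead_id, i, tr.times[i], tr.x[i], tr.y[i]))
        return pd.DataFrame(rows, columns=["bead_id", "frame", "t_s", "x_um", "y_um"])

    @classmethod
    def from_dataframe(cls, df) -> "TrajectorySet":
        trajs = []
        for bead_id, sub in df.groupby("bead_id"):
            sub = sub.sort_values("frame")
            trajs.append(
                Trajectory(
                    bead_id=int(bead_id),
                    times=sub["t_s"].to_numpy(),
                    x=sub["x_um"].to_numpy(),
                    y=sub["y_um"].to_numpy(),
                )
            )
        return cls(trajs)


@dataclass
class MSDCurve:
    """Lag-indexed mean squared displacement.

    ``lags_frames`` starts at 1; ``n_terms`` holds the number of overlapping
    windows averaged at each lag (``N - tau`` for a single bead, the number of
    contributing beads for an ensemble curve).  ``sem`` is populated only for
    ensemble curves.
    """

    lags_frames: np.ndarray
    lags_s: np.ndarray
    msd: np.ndarray  # um^2
    n_terms: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags_frames = np.asarray(self.lags_frames, dtype=int)
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_terms = np.asarray(self.n_terms, dtype=int)
        if np.any(self.msd < -1e-12):
            raise ValueError("msd must be non-negative")

    def at_lag(self, lag_s: float) -> float:
        """MSD value at the lag (in seconds) closest to ``lag_s``."""
        return float(self.msd[np.argmin(np.abs(self.lags_s - lag_s))])

    def to_dataframe(self):
        import pandas as pd

        d = {
            "lag_frames": self.lags_frames,
            "lag_s": self.lags_s,
            "msd_um2": self.msd,
            "n_terms": self.n_terms,
        }
        if self.sem is not None:
            d["sem"] = self.sem
        return pd.DataFrame(d)


def compute_msd(trajectory: Trajectory, max_lag: int | None = None) -> MSDCurve:
    """Overlapping-window MSD of one trajectory.

    Parameters
    ----------
    trajectory
        Uniformly sampled 2-D track.
    max_lag
        Largest lag in frames; defaults to ``N // 4`` (variance at larger
        lags grows too fast to be useful).
    """
    n = trajectory.n_frames
    if max_lag is None:
        max_lag = max(1, n // 4)
    if not 1 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in [1, {n - 1}], got {max_lag}")
    x, y = trajectory.x, trajectory.y
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, tau in enumerate(lags):
        dx = x[tau:] - x[:-tau]
        dy = y[tau:] - y[:-tau]
        msd[k] = np.mean(dx * dx + dy * dy)
    return MSDCurve(
        lags_frames=lags,
        lags_s=lags * trajectory.dt,
        msd=msd,
        n_terms=n - lags,
    )


def ensemble_msd(
    trajectories: TrajectorySet | Sequence[Trajectory],
    max_lag: int | None = None,
    weighting: str = "per_bead",
) -> MSDCurve:
    """Per-lag average of per-bead MSD curves.

    ``weighting='per_bead'`` (default) gives every bead equal weight;
    ``'pooled'`` weights each bead's contribution by its number of
    overlapping windows at that lag.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("empty trajectory set")
    if max_lag is None:
        max_lag = max(1, max(t.n_frames for t in trajs) // 4)
    usable = [t for t in trajs if t.n_frames > max_lag]
    if not usable:
        raise ValueError(f"no trajectory longer than max_lag={max_lag}")
    dt = usable[0].dt

    per_bead = [compute_msd(t, min(max_lag, t.n_frames - 1)) for t in usable]
    lags = np.arange(1, max_lag + 1)
    msd = np.full(max_lag, np.nan)
    sem = np.zeros(max_lag)
    n_beads = np.zeros(max_lag, dtype=int)
    for k, tau in enumerate(lags):
        vals, wts = [], []
        for c in per_bead:
            if tau <= c.lags_frames[-1]:
                vals.append(c.msd[tau - 1])
                wts.append(c.n_terms[tau - 1])
        vals = np.asarray(vals)
        n_beads[k] = len(vals)
        if weighting == "pooled":
            msd[k] = np.average(vals, weights=wts)
        else:
            msd[k] = vals.mean()
        if len(vals) > 1:
            sem[k] = vals.std(ddof=1) / np.sqrt(len(vals))
    return MSDCurve(lags_frames=lags, lags_s=lags * dt, msd=msd, n_terms=n_beads, sem=sem)


def correct_linear_drift(
    trajectories: TrajectorySet,
) -> tuple[TrajectorySet, np.ndarray]:
    """Estimate and remove a common linear drift.

    The drift velocity is the least-squares slope (per axis) of the
    ensemble-mean position versus time; it is subtracted from every
    trajectory relative to its first time point.  Returns the corrected set
    and the estimated drift as a 2-vector in um/s.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("empty trajectory set")
    n_max = max(t.n_frames for t in trajs)
    if n_max < 2:
        raise ValueError("need at least 2 frames to estimate drift")

    # ensemble-mean displacement from each bead's own start, per frame index
    sum_x = np.zeros(n_max)
    sum_y = np.zeros(n_max)
    count = np.zeros(n_max)
    for t in trajs:
        n = t.n_frames
        sum_x[:n] += t.x - t.x[0]
        sum_y[:n] += t.y - t.y[0]
        count[:n] += 1
    mask = count > 0
    mean_x = sum_x[mask] / count[mask]
    mean_y = sum_y[mask] / count[mask]
    dt = trajs[0].dt
    tt = np.arange(n_max)[mask] * dt
    vx = np.polyfit(tt, mean_x, 1)[0]
    vy = np.polyfit(tt, mean_y, 1)[0]

    corrected = []
    for t in trajs:
        rel_t = t.times - t.times[0]
        corrected.append(
            Trajectory(t.bead_id, t.times, t.x - vx * rel_t, t.y - vy * rel_t)
        )
    out = TrajectorySet(corrected, metadata=dict(trajectories.metadata)
                        if isinstance(trajectories, TrajectorySet) else {})
    drift = np.array([vx, vy])
    out.metadata["drift_estimate_um_per_s"] = drift.tolist()
    return out, drift


def fit_scaling(
    msd: MSDCurve, fit_range: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Log-log power-law fit of an MSD curve.

    ``fit_range`` is an inclusive window in frame lags.  Returns
    ``(anomalous_exponent, apparent_D)`` where the exponent is the log-log
    slope and ``apparent_D = exp(intercept) / 4`` (2-D convention
    ``msd = 4 D tau^alpha`` with tau in seconds).
    """
    if fit_range is None:
        lo, hi = int(msd.lags_frames[0]), int(msd.lags_frames[-1])
    else:
        lo, hi = fit_range
    sel = (msd.lags_frames >= lo) & (msd.lags_frames <= hi)
    if not sel.any():
        raise ValueError("fit_range selects no lags")
    m = msd.msd[sel]
    if np.any(m <= 0) or np.any(~np.isfinite(m)):
        raise ValueError("MSD must be strictly positive and finite on the fit range")
    logt = np.log(msd.lags_s[sel])
    logm = np.log(m)
    slope, intercept = np.polyfit(logt, logm, 1)
    return float(slope), float(np.exp(intercept) / 4.0)


def _values_at_lag(group, reference_lag: float) -> np.ndarray:
    vals = []
    for item in group:
        if isinstance(item, MSDCurve):
            vals.append(item.at_lag(reference_lag))
        else:
            vals.append(float(item))
    return np.asarray(vals)


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """Plain one-way ANOVA returning (F, df_between, df_within, p).

    Degenerate inputs are resolved explicitly: zero between-group variability
    gives F = 0, p = 1 (scipy returns nan when the within-group variance is
    also zero).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n_tot - k
    if ssb <= 1e-300:
        return 0.0, dfb, dfw, 1.0
    if ssw <= 1e-300:
        return float("inf"), dfb, dfw, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), dfb, dfw, p


def msd_dose_response(
    groups: Mapping[str, Iterable],
    reference_lag: float,
    vehicle: str | None = None,
) -> dict:
    """One-way ANOVA across dose groups on MSD at a reference lag.

    ``groups`` maps group name to either per-replicate ``MSDCurve`` objects
    or scalar MSD values already evaluated at the reference lag.  Pairwise
    Welch comparisons against the vehicle group are Holm-Sidak adjusted.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: _values_at_lag(v, reference_lag) for k, v in groups.items()}
    for name, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    names = list(arrays)
    if vehicle is None:
        vehicle = names[0]
    f, dfb, dfw, p = one_way_anova([arrays[n] for n in names])

    others = [n for n in names if n != vehicle]
    raw_p, t_stats = [], []
    for n in others:
        t, pv = stats.ttest_ind(arrays[vehicle], arrays[n], equal_var=False)
        t_stats.append(float(t))
        raw_p.append(float(pv) if np.isfinite(pv) else 1.0)
    adj = holm_sidak(raw_p)
    return {
        "method": "one_way_anova",
        "reference_lag_s": reference_lag,
        "F": f,
        "df": (dfb, dfw),
        "p": p,
        "vehicle": vehicle,
        "pairwise": [
            {"group": n, "t": t, "p_raw": pr, "p_adjusted": pa}
            for n, t, pr, pa in zip(others, t_stats, raw_p, adj)
        ],
    }


# ---------------------------------------------------------------------------
# detection and linking
# ---------------------------------------------------------------------------


def _refine_centroid(frame: np.ndarray, row: int, col: int, radius: int) -> tuple[float, float]:
    """Intensity-weighted sub-pixel centroid around a peak.

    Recentering the window on the running estimate (3 iterations) suppresses
    the pixel-locking bias of a single fixed window.
    """
    h, w = frame.shape
    r, c = float(row), float(col)
    for _ in range(3):
        r0, r1 = max(0, int(round(r)) - radius), min(h, int(round(r)) + radius + 1)
        c0, c1 = max(0, int(round(c)) - radius), min(w, int(round(c)) + radius + 1)
        win = frame[r0:r1, c0:c1].astype(float)
        win = win - win.min()
        total = win.sum()
        if total <= 0:
            return r, c
        rr, cc = np.mgrid[r0:r1, c0:c1]
        r = float((rr * win).sum() / total)
        c = float((cc * win).sum() / total)
    return r, c


def detect_and_link(
    movie,
    expected_diameter: int = 7,
    intensity_percentile: float = 99.0,
    max_displacement: float = 5.0,
    memory: int = 0,
    min_length: int = 10,
) -> TrajectorySet:
    """Detect bright spots in a movie and link them into trajectories.

    Spots are local maxima above the per-frame intensity percentile, refined
    to sub-pixel centroids.  Linking is greedy nearest-neighbour within
    ``max_displacement`` pixels per frame; a track survives up to ``memory``
    consecutive missed frames (gap positions are linearly interpolated so
    the output stays uniformly sampled).  Positions are returned in um.

    Parameters mirror common particle-tracking conventions:
    ``expected_diameter`` must be odd and >= 3.
    """
    frames = movie.frames
    if frames.shape[0] == 0:
        raise ValueError("empty movie")
    if expected_diameter < 3 or expected_diameter % 2 == 0:
        raise ValueError("expected_diameter must be odd and >= 3")
    if max_displacement < 1:
        raise ValueError("max_displacement must be >= 1")
    pixel_size = movie.pixel_size
    dt = 1.0 / movie.frame_rate
    radius = expected_diameter // 2

    # active track state: list of dicts
    active: list[dict] = []
    done: list[dict] = []
    n_detections = 0

    for fi in range(frames.shape[0]):
        frame = frames[fi]
        thresh = np.percentile(frame, intensity_percentile)
        mx = ndimage.maximum_filter(frame, size=expected_diameter, mode="nearest")
        peaks = np.argwhere((frame == mx) & (frame > thresh))
        dets = np.array(
            [_refine_centroid(frame, int(r), int(c), radius) for r, c in peaks]
        ).reshape(-1, 2)
        n_detections += len(dets)

        assigned_det = set()
        if active and len(dets):
            tree = cKDTree(dets)
            last_pos = np.array([t["pos"][-1] for t in active])
            dists, idx = tree.query(last_pos)
            order = np.argsort(dists)
            taken = set()
            for ti in order:
                di = idx[ti]
                if dists[ti] > max_displacement or di in taken:
                    continue
                tr = active[ti]
                gap = fi - tr["frames"][-1] - 1
                if gap > 0:  # fill the gap by linear interpolation
                    p0 = np.asarray(tr["pos"][-1])
                    p1 = dets[di]
                    for g in range(1, gap + 1):
                        frac = g / (gap + 1)
                        tr["pos"].append(tuple(p0 + frac * (p1 - p0)))
                        tr["frames"].append(tr["frames"][-1] + 1)
                tr["pos"].append(tuple(dets[di]))
                tr["frames"].append(fi)
                taken.add(di)
                assigned_det.add(di)

        # retire stale tracks
        still = []
        for tr in active:
            if fi - tr["frames"][-1] > memory:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        for di in range(len(dets)):
            if di not in assigned_det:
                active.append({"pos": [tuple(dets[di])], "frames": [fi]})

    done.extend(active)
    if n_detections == 0:
        warnings.warn("no detections above threshold; returning empty set")

    trajs = []
    bead_id = 0
    for tr in done:
        if len(tr["frames"]) < max(min_length, 2):
            continue
        fr = np.asarray(tr["frames"])
        pos = np.asarray(tr["pos"])  # (n, 2) as (row, col)
        trajs.append(
            Trajectory(
                bead_id=bead_id,
                times=fr * dt,
                x=pos[:, 1] * pixel_size,
                y=pos[:, 0] * pixel_size,
            )
        )
        bead_id += 1
    return TrajectorySet(
        trajs,
        metadata={
            "pixel_size": pixel_size,
            "frame_rate": movie.frame_rate,
            "expected_diameter": expected_diameter,
            "max_displacement": max_displacement,
        },
    )
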