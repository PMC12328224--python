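"""Migration speed and directional persistence from centroid tracks.

Speed is total path length divided by total tracking time.  Persistence is
summarised by the decay of the directional autocorrelation: the mean cosine
of the angle between normalised displacement vectors separated by a time lag,
pooled over all tracks of a cell line-substrate group.  The decorrelation
time — the first lag at which the mean cosine drops below 0.2 — is the
persistence proxy; if the profile never drops below the threshold within the
observable lags, the total trajectory time is reported instead and the
estimate is flagged as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError

_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered 2-D positions of one cell at a uniform frame interval."""

    track_id: str
    t_min: np.ndarray = field(repr=False)
    x_um: np.ndarray = field(repr=False)
    y_um: np.ndarray = field(repr=False)
    cell_line: str = ""
    substrate: str = ""

    def __post_init__(self):
        t = np.asarray(self.t_min, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        if not (t.size == x.size == y.size) or t.size < 3:
            raise InputError("trajectory needs >= 3 aligned (t, x, y) samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError("times must be strictly increasing")
        if np.ptp(dt) > _SPACING_RTOL * dt[0]:
            raise InputError("frame interval must be uniform")
        for name, arr in (("t_min", t), ("x_um", x), ("y_um", y)):
            object.__setattr__(self, name, arr)

    @property
    def frame_interval(self) -> float:
        return float(self.t_min[1] - self.t_min[0])

    @property
    def total_time(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])


@dataclass(frozen=True)
class AutocorrelationProfile:
    """Directional autocorrelation vs lag for one group of tracks."""

    lags_min: np.ndarray
    mean_cos: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_pairs: np.ndarray
    n_zero_skipped: int = 0


@dataclass(frozen=True)
class PersistenceEstimate:
    """Decorrelation time in minutes; censored when the profile never
    crossed the threshold and the total trajectory time was used instead."""

    decorrelation_time: float
    censored: bool
    threshold: float = 0.2


def trajectories_from_table(table: pd.DataFrame) -> list[Trajectory]:
    """Build Trajectory objects from a long table (see synthetic module)."""
    out = []
    for (line, substrate, tid), grp in table.groupby(
        ["cell_line", "substrate", "track_id"], sort=True
    ):
        grp = grp.sort_values("t_min")
        out.append(
            Trajectory(
                track_id=str(tid),
                t_min=grp["t_min"].to_numpy(),
                x_um=grp["x_um"].to_numpy(),
                y_um=grp["y_um"].to_numpy(),
                cell_line=str(line),
                substrate=str(substrate),
            )
        )
    return out


def compute_speed(traj: Trajectory) -> float:
    """Total path length / total tracking time (um/min)."""
    steps = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    return float(steps.sum() / traj.total_time)


def directional_autocorrelation(
    trajs: list[Trajectory], max_lag_steps: int | None = None
) -> AutocorrelationProfile:
    """Pooled mean cos(theta) between unit displacement vectors per lag.

    Lags are multiples of the frame interval.  Displacements of zero length
    carry no direction; cosine pairs touching them are skipped and counted.
    The 95% CI is a normal approximation on the pooled cosines per lag.
    """
    if not trajs:
        raise InputError("no trajectories supplied")
    dt = trajs[0].frame_interval
    n_steps_max = max(t.t_min.size - 1 for t in trajs)
    if max_lag_steps is None:
        max_lag_steps = n_steps_max - 1
    max_lag_steps = min(max_lag_steps, n_steps_max - 1)
    if max_lag_steps < 1:
        raise InputError("trajectories too short for any lag")

    pooled: list[list[float]] = [[] for _ in range(max_lag_steps)]
    n_zero_skipped = 0
    for traj in trajs:
        vx = np.diff(traj.x_um)
        vy = np.diff(traj.y_um)
        norm = np.hypot(vx, vy)
        ok = norm > 0
        n_v = vx.size
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(ok, vx / np.where(ok, norm, 1.0), np.nan)
            uy = np.where(ok, vy / np.where(ok, norm, 1.0), np.nan)
        for lag in range(1, min(max_lag_steps, n_v - 1) + 1):
            cosines = ux[:-lag] * ux[lag:] + uy[:-lag] * uy[lag:]
            valid = ok[:-lag] & ok[lag:]
            n_zero_skipped += int((~valid).sum())
            if valid.any():
                pooled[lag - 1].extend(cosines[valid].tolist())

    if all(len(p) == 0 for p in pooled):
        raise DegenerateDataError("all displacements have zero length")

    lags, means, lo, hi, ns = [], [], [], [], []
    for i, vals in enumerate(pooled):
        if not vals:
            continue
        arr = np.asarray(vals)
        m = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        lags.append((i + 1) * dt)
        means.append(m)
        lo.append(m - 1.96 * se)
        hi.append(m + 1.96 * se)
        ns.append(arr.size)
    return AutocorrelationProfile(
        lags_min=np.asarray(lags),
        mean_cos=np.asarray(means),
        ci_low=np.asarray(lo),
        ci_high=np.asarray(hi),
        n_pairs=np.asarray(ns, dtype=int),
        n_zero_skipped=n_zero_skipped,
    )


def decorrelation_time(
    profile: AutocorrelationProfile, total_time: float, threshold: float = 0.2
) -> PersistenceEstimate:
    """First lag with mean cos(theta) < threshold; censored at total_time.

    Applies the first-crossing rule: a profile that dips below the threshold
    and later recovers still decorrelates at the dip.
    """
    if profile.lags_min.size == 0:
        raise InputError("empty autocorrelation profile")
    below = profile.mean_cos < threshold
    if below.any():
        return PersistenceEstimate(
            decorrelation_time=float(profile.lags_min[int(np.argmax(below))]),
            censored=False,
            threshold=threshold,
        )
    return PersistenceEstimate(
        decorrelation_time=float(total_time), censored=True, threshold=threshold
    )


def speed_table(trajs: list[Trajectory]) -> pd.DataFrame:
    """Per-track speeds in the measurement schema (feature = speed)."""
    records = [
        (t.cell_line, t.substrate, "speed", t.track_id, compute_speed(t))
        for t in trajs
    ]
    return pd.DataFrame(
        records, columns=["cell_line", "substrate", "feature", "cell_id", "value"]
    )
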