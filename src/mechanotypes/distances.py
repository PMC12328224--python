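"""Distances between empirical distributions of single-cell measurements.

Cell line-substrate pairs are compared through their full value
distributions, not just their medians.  The workhorse is the Wasserstein-1
distance — the area between two empirical CDFs — computed by exact
integration over the pooled breakpoints (no binning, no kernel smoothing, so
no bandwidth choice can tilt the clustering).  W1 keeps growing as
distributions move apart, which makes it sensitive to heavy-tailed outlier
behaviour; the bounded Kolmogorov-Smirnov distance (sup-norm between ECDFs)
is provided as the standard comparator that saturates instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PairSample
from .errors import DegenerateDataError, InputError


def _ecdf_steps(x: np.ndarray, y: np.ndarray):
    """ECDF values of x and y on the pooled sorted support."""
    support = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), support, side="right") / x.size
    fy = np.searchsorted(np.sort(y), support, side="right") / y.size
    return support, fx, fy


def wasserstein1(x, y) -> float:
    """Exact 1-D Wasserstein-1 distance: integral of |F_x - F_y|.

    Both ECDFs are step functions constant between pooled breakpoints, so the
    integral is a finite sum of |F_x - F_y| times breakpoint gaps.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("samples must be non-empty")
    support, fx, fy = _ecdf_steps(x, y)
    widths = np.diff(support)
    return float(np.sum(np.abs(fx[:-1] - fy[:-1]) * widths))


def ks_distance(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov distance: sup |F_x - F_y| in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("samples must be non-empty")
    _, fx, fy = _ecdf_steps(x, y)
    return float(np.max(np.abs(fx - fy)))


METRICS = {"wasserstein1": wasserstein1, "ks": ks_distance}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between cell line-substrate pairs."""

    labels: tuple[tuple[str, str], ...]
    D: np.ndarray = field(repr=False)
    metric: str = "wasserstein1"

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape must match labels")
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        names = [f"{l}|{s}" for l, s in self.labels]
        return pd.DataFrame(self.D, index=names, columns=names)


def pairwise_distances(samples: list[PairSample], metric: str = "wasserstein1") -> DistanceMatrix:
    """Full distance matrix over pair samples of one feature.

    Labels are ordered lexicographically by (cell_line, substrate) so output
    is deterministic regardless of input order.
    """
    if len(samples) < 2:
        raise InputError("need at least 2 samples")
    features = {s.feature for s in samples}
    if len(features) != 1:
        raise InputError(f"mixed features in one distance matrix: {sorted(features)}")
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    fn = METRICS[metric]
    ordered = sorted(samples, key=lambda s: s.pair_id)
    n = len(ordered)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(ordered[i].values, ordered[j].values)
    return DistanceMatrix(
        labels=tuple(s.pair_id for s in ordered), D=D, metric=metric
    )


@dataclass(frozen=True)
class DensityEstimate:
    """Gaussian-kernel density on a regular grid; integrates to ~1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def class_kde(values, bandwidth: str | float = "silverman", n_grid: int = 512) -> DensityEstimate:
    """Gaussian KDE of pooled feature values for one phenotypic class.

    Grid spans the data plus three bandwidths on each side.  Silverman's rule
    is the default bandwidth; a constant sample has no spread to smooth and
    raises :class:`DegenerateDataError`.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise DegenerateDataError("KDE needs >= 2 distinct values")
    kde = stats.gaussian_kde(v, bw_method=bandwidth if bandwidth != "silverman" else "silverman")
    bw = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, n_grid)
    return DensityEstimate(grid=grid, density=kde(grid), bandwidth=bw)
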