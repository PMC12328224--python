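"""Synthetic generators for every input the pipeline consumes.

Three generators stand in for the experimental dataset:

* :func:`simulate_measurements` — long-format single-cell feature tables with
  planted class structure.  Per-pair distributions are right-skewed
  (lognormal or gamma), matching the skew of real morphology/stiffness/speed
  data that motivates median summaries and distribution-level clustering.
* :func:`simulate_trajectories` — persistent random walks sampled at a fixed
  frame interval (default 5 min over 1-3 h), emulating nucleus-tracked
  centroid trajectories.  Headings evolve by Gaussian increments, which gives
  the closed-form lag autocorrelation ``exp(-lag * turn_sd**2 / 2)`` used by
  the tests.
* :func:`simulate_force_curve` — spherical-probe Hertz force-indentation
  curves (1 um silica bead, soft cantilever) with an optional pre-contact
  baseline and additive Gaussian force noise.

All three are deterministic given their integer seed; independent streams are
derived by seed-sequence spawning so generators never share randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MEASUREMENT_COLUMNS, SUBSTRATES
from .errors import ConfigurationError

TRAJECTORY_COLUMNS = ("cell_line", "substrate", "track_id", "t_min", "x_um", "y_um")


# ---------------------------------------------------------------------------
# measurement tables with planted classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """One planted phenotypic class: a positive right-skewed value family.

    families:
      ``lognormal``     — params (mu, sigma) of log-values; median exp(mu).
      ``gamma``         — params (shape, scale); strictly positive support.
      ``lognormal_mix`` — params (mu, sigma, tail_mu, tail_sigma, tail_weight):
        a lognormal bulk contaminated by a far lognormal tail component.
        Used for outlier-like classes whose KS distance to the bulk-matched
        class is capped at ``tail_weight`` while their W1 distance grows with
        the tail location.
    An optional additive ``offset`` shifts the support (e.g. aspect ratio
    = 1 + lognormal).
    """

    class_id: int
    family: str
    params: tuple[float, ...]
    offset: float = 0.0

    def __post_init__(self):
        if self.family not in ("lognormal", "gamma", "lognormal_mix"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ConfigurationError("lognormal sigma must be > 0")
        if self.family == "gamma" and (self.params[0] <= 0 or self.params[1] <= 0):
            raise ConfigurationError("gamma shape and scale must be > 0")
        if self.family == "lognormal_mix":
            _, sigma, _, tail_sigma, w = self.params
            if sigma <= 0 or tail_sigma <= 0 or not 0 < w < 1:
                raise ConfigurationError("mixture needs positive sigmas, 0 < tail_weight < 1")

    def cdf(self, x) -> np.ndarray:
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm.cdf(x, s=sigma, scale=np.exp(mu), loc=self.offset)
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma.cdf(x, a=shape, scale=scale, loc=self.offset)
        mu, sigma, tail_mu, tail_sigma, w = self.params
        return (1 - w) * stats.lognorm.cdf(x, s=sigma, scale=np.exp(mu), loc=self.offset) + \
            w * stats.lognorm.cdf(x, s=tail_sigma, scale=np.exp(tail_mu), loc=self.offset)

    def theoretical_median(self) -> float:
        if self.family == "lognormal":
            return self.offset + float(np.exp(self.params[0]))
        if self.family == "gamma":
            shape, scale = self.params
            return float(stats.gamma.median(a=shape, scale=scale, loc=self.offset))
        from scipy.optimize import brentq

        lo, hi = self.offset + 1e-12, self.offset + np.exp(self.params[2]) * 1e3
        return float(brentq(lambda x: self.cdf(x) - 0.5, lo, hi))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            mu, sigma = self.params
            return self.offset + rng.lognormal(mean=mu, sigma=sigma, size=n)
        if self.family == "gamma":
            shape, scale = self.params
            return self.offset + rng.gamma(shape=shape, scale=scale, size=n)
        mu, sigma, tail_mu, tail_sigma, w = self.params
        from_tail = rng.random(n) < w
        bulk = rng.lognormal(mean=mu, sigma=sigma, size=n)
        tail = rng.lognormal(mean=tail_mu, sigma=tail_sigma, size=n)
        return self.offset + np.where(from_tail, tail, bulk)


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a planted-class measurement table.

    Each class contributes ``pairs_per_class`` cell line-substrate pairs with
    ``cells_per_pair`` i.i.d. single-cell values drawn from its family.
    """

    classes: tuple[ClassSpec, ...]
    pairs_per_class: int | tuple[int, ...] = 12
    cells_per_pair: int = 100
    feature: str = "area"
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_pair < 1:
            raise ConfigurationError("cells_per_pair must be >= 1")
        if min(self.class_sizes) < 1:
            raise ConfigurationError("pairs_per_class must be >= 1")
        if len(self.class_sizes) != len(self.classes):
            raise ConfigurationError("per-class pair counts must match classes")
        if len({c.class_id for c in self.classes}) != len(self.classes):
            raise ConfigurationError("class_ids must be distinct")

    @property
    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.pairs_per_class, int):
            return (self.pairs_per_class,) * len(self.classes)
        return tuple(self.pairs_per_class)


def default_area_design(seed: int = 0) -> SyntheticDesign:
    """Four well-separated lognormal area classes.

    Class medians span 150-1200 um^2 with comparable absolute within-class
    spread (sd ~55 um^2, so sigma = sd/median in log space): separation is in
    location, and no single class dominates the dispersion budget of the
    distance matrix.
    """
    medians = (150.0, 400.0, 750.0, 1200.0)
    classes = tuple(
        ClassSpec(class_id=i, family="lognormal", params=(np.log(m), 55.0 / m))
        for i, m in enumerate(medians)
    )
    return SyntheticDesign(classes=classes, feature="area", seed=seed)


#: class_id of the heavy-tailed outlier in :func:`outlier_contrast_design`.
OUTLIER_CLASS_ID = 99


def outlier_contrast_design(seed: int = 0) -> SyntheticDesign:
    """Three base area classes plus one heavy-tailed outlier pair.

    The outlier's bulk coincides with the top class (median 750 um^2) but 15%
    of its mass sits in a far upper tail around 8 x 10^4 um^2.  Its KS
    distance to the matched class is therefore capped near 0.15 — inside the
    sampling noise of within-class KS values — and its KS distances to the
    remaining classes saturate at the same ~0.85-1.0 level as the
    base-to-base separations, while its Wasserstein-1 distance to *every*
    base class (~10^4) exceeds the largest base-to-base W1 (~600) by more
    than an order of magnitude.  W1-based clustering isolates the outlier as
    its own class; KS-based clustering, blind to tail mass beyond its bound,
    folds it into the bulk-matched class.
    """
    medians = (150.0, 400.0, 750.0)
    classes = tuple(
        ClassSpec(class_id=i, family="lognormal", params=(np.log(m), 55.0 / m))
        for i, m in enumerate(medians)
    ) + (
        ClassSpec(
            class_id=OUTLIER_CLASS_ID,
            family="lognormal_mix",
            params=(np.log(750.0), 55.0 / 750.0, np.log(8.0e4), 0.5, 0.15),
        ),
    )
    return SyntheticDesign(
        classes=classes, pairs_per_class=(12, 12, 12, 1), feature="area", seed=seed
    )


def simulate_measurements(
    design: SyntheticDesign,
) -> tuple[pd.DataFrame, dict[tuple[str, str], int]]:
    """Generate a measurement table plus the ground-truth pair -> class map.

    Pair identities are synthetic cell lines cycled over the seven substrate
    labels, so pairs are valid (cell_line, substrate) keys.  Identical seed
    yields bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    records = []
    labels: dict[tuple[str, str], int] = {}
    pair_index = 0
    for cls, n_pairs in zip(design.classes, design.class_sizes):
        for _ in range(n_pairs):
            line = f"SYN{pair_index // len(SUBSTRATES):03d}"
            substrate = SUBSTRATES[pair_index % len(SUBSTRATES)]
            values = cls.sample(design.cells_per_pair, rng)
            for j, v in enumerate(values):
                records.append((line, substrate, design.feature, f"c{j:05d}", v))
            labels[(line, substrate)] = cls.class_id
            pair_index += 1
    table = pd.DataFrame(records, columns=list(MEASUREMENT_COLUMNS))
    return table, labels


# ---------------------------------------------------------------------------
# persistent random-walk trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkSpec:
    """Heading-increment persistent random walk.

    Per frame the heading gains a N(0, turn_sd^2) increment and the cell
    advances ``mean_speed * frame_interval`` along it.  ``turn_sd`` is in
    radians per step; ``turn_sd = 0`` is ballistic motion.
    """

    mean_speed: float = 0.5       # um/min
    turn_sd: float = 0.6          # rad per 5-min step
    frame_interval: float = 5.0   # min
    duration: float = 180.0       # min, 1-3 h of tracking
    n_tracks: int = 50
    seed: int = 0
    cell_line: str = "SYN000"
    substrate: str = "Glass"

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.duration < 2 * self.frame_interval:
            raise ConfigurationError("duration must cover at least two frames")
        if self.mean_speed < 0 or self.turn_sd < 0:
            raise ConfigurationError("mean_speed and turn_sd must be >= 0")


def simulate_trajectories(spec: WalkSpec) -> pd.DataFrame:
    """Simulate tracks; returns a long table with TRAJECTORY_COLUMNS."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    n_steps = int(np.floor(spec.duration / spec.frame_interval))
    t = np.arange(n_steps + 1) * spec.frame_interval
    step_len = spec.mean_speed * spec.frame_interval
    frames = []
    for k in range(spec.n_tracks):
        theta0 = rng.uniform(0, 2 * np.pi)
        increments = rng.normal(0.0, spec.turn_sd, size=n_steps)
        headings = theta0 + np.concatenate([[0.0], np.cumsum(increments)])[:n_steps]
        dx = step_len * np.cos(headings)
        dy = step_len * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": spec.cell_line,
                    "substrate": spec.substrate,
                    "track_id": f"t{k:04d}",
                    "t_min": t,
                    "x_um": x,
                    "y_um": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hertz force curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Spherical-indenter Hertz curve generator.

    ``contact_offset`` places the contact point along the sampled axis; the
    pre-contact segment is flat (zero force plus noise), emulating the
    baseline of a raw approach curve.  Defaults reflect a 1 um diameter bead
    and an incompressible cell (Poisson ratio 0.5).
    """

    E_true: float = 1000.0        # Pa
    bead_radius: float = 0.5      # um
    poisson: float = 0.5
    max_indentation: float = 1000.0  # nm sampled along the axis
    step: float = 10.0            # nm between samples
    noise_sd: float = 0.0         # N, additive Gaussian force noise
    contact_offset: float = 0.0   # nm
    seed: int = 0

    def __post_init__(self):
        if self.E_true <= 0:
            raise ConfigurationError("E_true must be > 0")
        if not 0 <= self.poisson < 1:
            raise ConfigurationError("poisson must lie in [0, 1)")
        if self.max_indentation < 500:
            raise ConfigurationError("max_indentation must be >= 500 nm")
        if self.bead_radius <= 0 or self.step <= 0:
            raise ConfigurationError("bead_radius and step must be > 0")


def hertz_force(delta_nm, E_pa: float, bead_radius_um: float, poisson: float = 0.5):
    """Hertz sphere-on-half-space force (N) at indentation depth delta (nm).

    f = (4/3) * E * sqrt(R) * delta^(3/2) / (1 - nu^2), evaluated in SI.
    """
    delta_m = np.asarray(delta_nm, dtype=float) * 1e-9
    R_m = bead_radius_um * 1e-6
    return (4.0 / 3.0) * E_pa * np.sqrt(R_m) * np.clip(delta_m, 0, None) ** 1.5 / (
        1.0 - poisson**2
    )


def simulate_force_curve(spec: CurveSpec, curve_id: str = "curve0",
                         cell_id: str = "cell0", location_id: str = "loc0"):
    """Generate one force curve; returns an ``afm.ForceCurve``.

    The indentation axis runs 0..max_indentation in ``step`` increments;
    samples before ``contact_offset`` carry zero deterministic force.
    """
    from .afm import ForceCurve  # local import to avoid cycle

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    z = np.arange(0.0, spec.max_indentation + 0.5 * spec.step, spec.step)
    delta = z - spec.contact_offset
    f = hertz_force(delta, spec.E_true, spec.bead_radius, spec.poisson)
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, size=f.size)
    return ForceCurve(
        curve_id=curve_id,
        indentation_nm=z,
        force_N=f,
        bead_radius_um=spec.bead_radius,
        spring_constant=0.06,
        cell_id=cell_id,
        location_id=location_id,
    )
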