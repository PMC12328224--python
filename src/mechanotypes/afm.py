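"""Hertz-model fitting of AFM force-indentation curves.

A spherical probe indenting a homogeneous, incompressible elastic half-space
obeys

    f = (4/3) * E * sqrt(R) * delta^(3/2) / (1 - nu^2)

with f the force on the cell, E the Young's modulus (Pa), R the bead radius,
delta the indentation depth and nu the Poisson ratio (0.5 for an
incompressible cell).  Only the first 500 nm of indentation is fit, where the
half-space assumption is least strained.  Because the model is linear in E,
the least-squares solution is closed-form:

    E_hat = sum(f_i * x_i) / (c * sum(x_i^2)),   x_i = delta_i^(3/2),
    c = (4/3) * sqrt(R) / (1 - nu^2)

which is exact, deterministic and equivalent to iterative nonlinear least
squares on this one-parameter model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MEASUREMENT_COLUMNS
from .errors import DetectionError, InputError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForceCurve:
    """One indentation curve: depth samples (nm, ascending) and force (N).

    ``indentation_nm`` is depth past the contact point for aligned curves;
    raw approach curves (with a pre-contact baseline) use the same container
    and are aligned via :func:`detect_contact_point`.
    """

    curve_id: str
    indentation_nm: np.ndarray = field(repr=False)
    force_N: np.ndarray = field(repr=False)
    bead_radius_um: float = 0.5
    spring_constant: float = 0.06  # N/m, informational (f = k * deflection)
    cell_id: str = ""
    location_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.indentation_nm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if z.size != f.size or z.size < 5:
            raise InputError("indentation and force must share length >= 5")
        if np.any(np.diff(z) <= 0):
            raise InputError("indentation axis must be strictly increasing")
        if self.bead_radius_um <= 0:
            raise InputError("bead_radius_um must be > 0")
        object.__setattr__(self, "indentation_nm", z)
        object.__setattr__(self, "force_N", f)


@dataclass(frozen=True)
class HertzFit:
    """Result of one Hertz fit.  ``ok`` is False when the least-squares
    solution was non-positive (e.g. a retracting or upside-down curve); a
    failed fit never reports a modulus."""

    curve_id: str
    E: float                  # Pa; NaN when ok is False
    ok: bool
    poisson: float = 0.5
    window_nm: float = 500.0
    n_points: int = 0
    residual_rms: float = float("nan")  # N
    cell_id: str = ""
    location_id: str = ""


def fit_hertz(curve: ForceCurve, poisson: float = 0.5, window_nm: float = 500.0) -> HertzFit:
    """Closed-form Hertz fit over samples with 0 < delta <= window_nm."""
    delta = curve.indentation_nm
    mask = (delta > 0) & (delta <= window_nm)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"curve {curve.curve_id}: {int(mask.sum())} samples in (0, {window_nm}] nm, need >= 3"
        )
    x = (delta[mask] * 1e-9) ** 1.5
    f = curve.force_N[mask]
    c = (4.0 / 3.0) * np.sqrt(curve.bead_radius_um * 1e-6) / (1.0 - poisson**2)
    E = float(np.dot(f, x) / (c * np.dot(x, x)))
    ok = E > 0
    resid = f - c * E * x if ok else f
    return HertzFit(
        curve_id=curve.curve_id,
        E=E if ok else float("nan"),
        ok=ok,
        poisson=poisson,
        window_nm=window_nm,
        n_points=int(mask.sum()),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        cell_id=curve.cell_id,
        location_id=curve.location_id,
    )


def detect_contact_point(
    curve: ForceCurve,
    poisson: float = 0.5,
    min_baseline: int = 2,
    min_contact: int = 3,
) -> int:
    """Locate the contact point on a raw approach curve.

    Fits a two-segment model — flat baseline before index j, Hertz growth
    beyond it (depth measured from sample j) — and returns the j minimising
    the total squared residual.  Raises :class:`DetectionError` when no split
    beats a pure-baseline explanation, i.e. the curve never actually contacts.
    """
    z = curve.indentation_nm
    f = curve.force_N
    n = z.size
    if n < min_baseline + min_contact:
        raise DetectionError(f"curve {curve.curve_id}: too short for a two-segment fit")
    c = (4.0 / 3.0) * np.sqrt(curve.bead_radius_um * 1e-6) / (1.0 - poisson**2)

    best_j, best_sse, best_E = -1, np.inf, np.nan
    for j in range(min_baseline, n - min_contact + 1):
        baseline = float(np.mean(f[:j]))
        x = ((z[j:] - z[j]) * 1e-9) ** 1.5
        y = f[j:] - baseline
        denom = float(np.dot(x, x))
        E = float(np.dot(y, x) / (c * denom)) if denom > 0 else 0.0
        resid_post = y - c * max(E, 0.0) * x
        sse = float(np.sum((f[:j] - baseline) ** 2) + np.sum(resid_post**2))
        if sse < best_sse:
            best_j, best_sse, best_E = j, sse, E

    if best_j < 0 or not best_E > 0:
        raise DetectionError(f"curve {curve.curve_id}: no admissible contact point")
    # reject pure-baseline curves: post-contact rise must exceed baseline noise
    baseline_sd = float(np.std(f[:best_j]))
    rise = float(np.mean(f[-min_contact:]) - np.mean(f[:best_j]))
    if rise <= 3.0 * baseline_sd:
        raise DetectionError(f"curve {curve.curve_id}: no contact detected (flat curve)")
    return best_j


def align_at_contact(curve: ForceCurve, contact_index: int) -> ForceCurve:
    """Re-reference a raw curve so depth and force are zero at contact."""
    z = curve.indentation_nm
    f = curve.force_N
    baseline = float(np.mean(f[:contact_index])) if contact_index > 0 else 0.0
    return ForceCurve(
        curve_id=curve.curve_id,
        indentation_nm=z[contact_index:] - z[contact_index],
        force_N=f[contact_index:] - baseline,
        bead_radius_um=curve.bead_radius_um,
        spring_constant=curve.spring_constant,
        cell_id=curve.cell_id,
        location_id=curve.location_id,
    )


def curves_to_frame(curves: list[ForceCurve]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialise curves into a long samples frame plus a probe sidecar."""
    samples = pd.concat(
        [
            pd.DataFrame(
                {
                    "curve_id": c.curve_id,
                    "indentation_nm": c.indentation_nm,
                    "force_N": c.force_N,
                }
            )
            for c in curves
        ],
        ignore_index=True,
    )
    sidecar = pd.DataFrame(
        [
            (c.curve_id, c.cell_id, c.location_id, c.bead_radius_um, c.spring_constant)
            for c in curves
        ],
        columns=["curve_id", "cell_id", "location_id", "bead_radius_um", "spring_constant"],
    )
    return samples, sidecar


def curves_from_frame(samples: pd.DataFrame, sidecar: pd.DataFrame) -> list[ForceCurve]:
    """Inverse of :func:`curves_to_frame`."""
    meta = sidecar.set_index("curve_id")
    out = []
    for cid, grp in samples.groupby("curve_id", sort=True):
        grp = grp.sort_values("indentation_nm")
        row = meta.loc[cid]
        out.append(
            ForceCurve(
                curve_id=str(cid),
                indentation_nm=grp["indentation_nm"].to_numpy(),
                force_N=grp["force_N"].to_numpy(),
                bead_radius_um=float(row["bead_radius_um"]),
                spring_constant=float(row["spring_constant"]),
                cell_id=str(row["cell_id"]),
                location_id=str(row["location_id"]),
            )
        )
    return out


def aggregate_stiffness(
    fits: list[HertzFit], cell_line: str, substrate: str
) -> pd.DataFrame:
    """Turn successful fits into stiffness rows of the measurement schema.

    Each indentation (typically three sites per cell) contributes its own
    record: the stiffness distribution is per-indentation, not per-cell,
    because within-cell positional variability is part of the measured
    heterogeneity.  Failed fits are excluded and logged.
    """
    records = []
    for fit in fits:
        if not fit.ok or not np.isfinite(fit.E):
            logger.info("excluding failed Hertz fit %s (cell %s)", fit.curve_id, fit.cell_id)
            continue
        cell_id = f"{fit.cell_id}:{fit.location_id}" if fit.location_id else fit.cell_id
        records.append((cell_line, substrate, "stiffness", cell_id, fit.E))
    return pd.DataFrame(records, columns=list(MEASUREMENT_COLUMNS))
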