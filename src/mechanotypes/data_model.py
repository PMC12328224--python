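"""Shared data model for single-cell mechanophenotyping tables.

The unit of analysis is the *cell line-substrate pair*: one cell line measured
on one of seven substrate conditions (polyacrylamide or hyaluronic-acid gels
of defined stiffness coated with collagen I or fibronectin, or glass).  All
single-cell measurements travel in one long-format table with columns
``cell_line, substrate, feature, cell_id, value``; substrate and feature
labels come from closed vocabularies so that groups can never fragment
silently over spelling variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    MetadataError,
    SchemaError,
    ValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

#: The seven substrate conditions (gel stiffness x ligand, plus glass).
SUBSTRATES: tuple[str, ...] = (
    "500Pa_Coll",
    "500Pa_FN",
    "30kPa_Coll",
    "30kPa_FN",
    "HA_Coll",
    "HA_FN",
    "Glass",
)

#: The eight tissue types represented in the panel.
TISSUES: tuple[str, ...] = (
    "skin",
    "prostate",
    "pancreas",
    "ovary",
    "lung",
    "colon",
    "breast",
    "brain",
)

#: Measured physical features and their units.
FEATURE_UNITS: Mapping[str, str] = {
    "area": "um^2",
    "aspect_ratio": "dimensionless",
    "circularity": "dimensionless",
    "stiffness": "Pa",
    "speed": "um/min",
}

FEATURES: tuple[str, ...] = tuple(FEATURE_UNITS)

MEASUREMENT_COLUMNS = ("cell_line", "substrate", "feature", "cell_id", "value")
METADATA_COLUMNS = ("cell_line", "tissue", "malignant")


def feature_value_ok(feature: str, value: float) -> bool:
    """Whether ``value`` satisfies the invariant of ``feature``.

    area > 0; aspect_ratio >= 1; circularity in (0, 1]; stiffness > 0;
    speed >= 0.  NaN never validates.
    """
    if not np.isfinite(value):
        return False
    if feature == "area" or feature == "stiffness":
        return value > 0
    if feature == "aspect_ratio":
        return value >= 1
    if feature == "circularity":
        return 0 < value <= 1
    if feature == "speed":
        return value >= 0
    raise VocabularyError(f"unknown feature label: {feature!r}")


@dataclass(frozen=True)
class CellLineMeta:
    """Annotation for one cell line: tissue of origin and malignancy."""

    name: str
    tissue: str
    malignant: bool

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise VocabularyError(
                f"unknown tissue {self.tissue!r} for cell line {self.name!r}; "
                f"expected one of {TISSUES}"
            )


@dataclass(frozen=True)
class PairSample:
    """All values of one feature for one cell line-substrate pair.

    ``values`` are sorted ascending at construction; ``n`` equals their count.
    """

    cell_line: str
    substrate: str
    feature: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValidationError("PairSample requires a non-empty value set")
        object.__setattr__(self, "values", v)

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.cell_line, self.substrate)

    @property
    def n(self) -> int:
        return int(self.values.size)


def read_metadata(path: str | Path) -> dict[str, CellLineMeta]:
    """Read a metadata CSV (cell_line, tissue, malignant) into a dict."""
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"metadata file missing columns: {sorted(missing)}")
    meta: dict[str, CellLineMeta] = {}
    for row in df.itertuples(index=False):
        name = str(row.cell_line)
        if name in meta:
            raise DuplicateKeyError(f"duplicate cell line in metadata: {name!r}")
        malignant = str(row.malignant).strip().lower() in ("true", "1", "yes")
        meta[name] = CellLineMeta(name=name, tissue=str(row.tissue), malignant=malignant)
    return meta


def write_metadata(meta: Mapping[str, CellLineMeta], path: str | Path) -> None:
    rows = [(m.name, m.tissue, m.malignant) for m in meta.values()]
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS))
    df.sort_values("cell_line", inplace=True)
    df.to_csv(path, index=False)


def validate_measurements(
    df: pd.DataFrame, meta: Mapping[str, CellLineMeta] | None = None
) -> pd.DataFrame:
    """Validate a long-format measurement frame against the shared schema.

    Returns the validated frame with canonical column order and dtypes.
    Raises :class:`SchemaError`, :class:`VocabularyError`,
    :class:`MetadataError`, :class:`ValidationError` (with offending row
    numbers) or :class:`DuplicateKeyError`.
    """
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"measurement table missing columns: {sorted(missing)}")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    bad_sub = sorted(set(df["substrate"]) - set(SUBSTRATES))
    if bad_sub:
        raise VocabularyError(f"unknown substrate labels: {bad_sub}")
    bad_feat = sorted(set(df["feature"]) - set(FEATURES))
    if bad_feat:
        raise VocabularyError(f"unknown feature labels: {bad_feat}")
    if meta is not None:
        bad_lines = sorted(set(df["cell_line"]) - set(meta))
        if bad_lines:
            raise MetadataError(f"cell lines absent from metadata: {bad_lines}")

    ok = np.fromiter(
        (feature_value_ok(f, v) for f, v in zip(df["feature"], df["value"])),
        dtype=bool,
        count=len(df),
    )
    if not ok.all():
        rows = df.index[~ok].tolist()
        raise ValidationError(
            f"{len(rows)} rows violate feature invariants (rows {rows[:20]}"
            f"{'...' if len(rows) > 20 else ''})",
            rows=rows,
        )

    keys = df[["cell_line", "substrate", "feature", "cell_id"]]
    dup = keys.duplicated()
    if dup.any():
        raise DuplicateKeyError(
            f"duplicate measurement keys at rows {df.index[dup].tolist()[:20]}"
        )
    return df


def read_measurements(
    path: str | Path, meta: Mapping[str, CellLineMeta] | None = None
) -> pd.DataFrame:
    """Read and validate a measurement CSV (see module docstring for schema)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return validate_measurements(pd.read_csv(p), meta=meta)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table with deterministic column order and row sort."""
    out = df.loc[:, list(MEASUREMENT_COLUMNS)].sort_values(
        list(MEASUREMENT_COLUMNS[:4]), kind="mergesort"
    )
    out.to_csv(path, index=False)


def extract_pair_samples(
    table: pd.DataFrame, feature: str, min_n: int = 25
) -> list[PairSample]:
    """Collect per-(cell line, substrate) samples of one feature.

    Pairs with fewer than ``min_n`` values are excluded and logged, mirroring
    the eligibility rule that a pair enters distribution-level analyses only
    with at least 25 measurements.  Returned samples are ordered
    lexicographically by (cell_line, substrate).
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    if feature not in FEATURES:
        raise VocabularyError(f"unknown feature label: {feature!r}")
    sub = table[table["feature"] == feature]
    samples: list[PairSample] = []
    n_excluded = 0
    for (line, substrate), grp in sorted(
        sub.groupby(["cell_line", "substrate"], sort=False), key=lambda kv: kv[0]
    ):
        if len(grp) >= min_n:
            samples.append(
                PairSample(line, substrate, feature, grp["value"].to_numpy())
            )
        else:
            n_excluded += 1
            logger.info(
                "excluding pair (%s, %s): n=%d < min_n=%d for feature %s",
                line, substrate, len(grp), min_n, feature,
            )
    if n_excluded:
        logger.info("%d pairs excluded by the n>=%d rule", n_excluded, min_n)
    return samples


def median_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell_line, substrate, feature) sample median and count.

    The median of the raw single-cell values is the population-level
    representative used throughout, chosen because the per-pair distributions
    are right-skewed.  Even-n median is the mean of the two central order
    statistics.
    """
    if len(table) == 0:
        return pd.DataFrame(
            columns=["cell_line", "substrate", "feature", "median", "n"]
        )
    out = (
        table.groupby(["cell_line", "substrate", "feature"], sort=True)["value"]
        .agg(median="median", n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
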