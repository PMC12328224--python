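"""End-to-end orchestration: simulate/load -> distances -> mechanotypes -> sensitivity.

``run_pipeline`` wires the stages in dependency order, writes every stage
output as CSV/JSON under an output directory, and returns a run manifest
(config snapshot, seed, per-stage row counts, warnings) sufficient to re-run
the deterministic stages bit-identically.  Configuration can come from a YAML
document (see :func:`load_config`).

``fetch_study_data`` is the optional hook for the deposited experimental
dataset; it needs network access, is never exercised by the test suite
beyond its error paths, and routes downloaded tables through a user-editable
column-mapping file into the shared measurement schema.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.request
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ClusteringConfig, discover_mechanotypes, mechanotype_report
from .data_model import extract_pair_samples, median_summary, read_measurements
from .distances import pairwise_distances
from .errors import ConfigurationError, FetchError, MappingError, StageError
from .sensitivity import substrate_sensitivity_table
from .synthetic import SyntheticDesign, default_area_design, simulate_measurements

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either a synthetic design or real input paths, plus stage options."""

    outdir: str = "results/pipeline"
    seed: int = 0
    features: tuple[str, ...] = ("area",)
    measurements_path: str | None = None
    metadata_path: str | None = None
    synthetic: SyntheticDesign | None = None
    metric: str = "wasserstein1"
    min_n: int = 25
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    run_sensitivity: bool = True
    n_perm: int = 2000

    def __post_init__(self):
        if self.synthetic is None and self.measurements_path is None:
            raise ConfigurationError(
                "config needs either a synthetic design or a measurements path"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "clustering" in doc:
        doc["clustering"] = ClusteringConfig(**doc["clustering"])
    if "synthetic" in doc and doc["synthetic"] is not None:
        doc["synthetic"] = SyntheticDesign(**doc["synthetic"])
    if doc.get("synthetic") is None and doc.get("measurements_path") is None:
        doc["synthetic"] = default_area_design(seed=int(doc.get("seed", 0)))
    return PipelineConfig(**doc)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, rows: int, t0: float):
        self.stages.append(
            {"stage": stage, "rows": int(rows), "seconds": round(time.perf_counter() - t0, 3)}
        )


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns (manifest, results dict).

    Stage outputs land under ``config.outdir``; a stage failure raises
    :class:`StageError` naming the stage.  All randomness derives from
    ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in vars(config).items()
        },
        version=__version__,
        seed=config.seed,
    )
    results: dict = {}

    # --- input stage ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.synthetic is not None:
            table, planted = simulate_measurements(config.synthetic)
            results["planted_labels"] = planted
        else:
            from .data_model import read_metadata

            meta = read_metadata(config.metadata_path) if config.metadata_path else None
            table = read_measurements(config.measurements_path, meta=meta)
    except Exception as exc:  # noqa: BLE001 - wrapped with stage name
        raise StageError("input", str(exc)) from exc
    results["measurements"] = table
    table.to_csv(outdir / "measurements.csv", index=False)
    manifest.record("input", len(table), t0)

    # --- median summaries -------------------------------------------------
    t0 = time.perf_counter()
    medians = median_summary(table)
    medians.to_csv(outdir / "median_summary.csv", index=False)
    results["medians"] = medians
    manifest.record("medians", len(medians), t0)

    # --- distances + mechanotypes per feature -----------------------------
    for feature in config.features:
        t0 = time.perf_counter()
        try:
            samples = extract_pair_samples(table, feature, min_n=config.min_n)
            dm = pairwise_distances(samples, metric=config.metric)
            dm.to_frame().to_csv(outdir / f"distances_{feature}_{config.metric}.csv")
        except Exception as exc:
            raise StageError(f"distances:{feature}", str(exc)) from exc
        manifest.record(f"distances:{feature}", dm.n, t0)

        t0 = time.perf_counter()
        try:
            cfg = ClusteringConfig(
                **{**asdict(config.clustering), "seed": config.seed}
            )
            mres = discover_mechanotypes(dm, cfg)
            report, kdes = mechanotype_report(mres.membership, samples)
        except Exception as exc:
            raise StageError(f"mechanotypes:{feature}", str(exc)) from exc
        mres.selection.per_k.to_csv(outdir / f"model_selection_{feature}.csv", index=False)
        report.to_csv(outdir / f"membership_{feature}.csv", index=False)
        kde_rows = [
            pd.DataFrame(
                {"grid": kde.grid, "density": kde.density, "class_id": cls, "feature": feature}
            )
            for cls, kde in kdes.items()
        ]
        if kde_rows:
            pd.concat(kde_rows, ignore_index=True).to_csv(
                outdir / f"class_kde_{feature}.csv", index=False
            )
        results[f"mechanotypes:{feature}"] = mres
        results[f"membership:{feature}"] = report
        manifest.record(f"mechanotypes:{feature}", len(report), t0)

    # --- substrate sensitivity -------------------------------------------
    if config.run_sensitivity:
        t0 = time.perf_counter()
        try:
            sens = substrate_sensitivity_table(
                table,
                features=list(config.features),
                min_n=config.min_n,
                n_perm=config.n_perm,
                seed=config.seed,
            )
        except Exception as exc:
            raise StageError("sensitivity", str(exc)) from exc
        sens.to_csv(outdir / "substrate_sensitivity.csv", index=False)
        results["sensitivity"] = sens
        manifest.record("sensitivity", len(sens), t0)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
    return manifest, results


# ---------------------------------------------------------------------------
# optional download of the deposited study data
# ---------------------------------------------------------------------------

FIGSHARE_DOI = "10.6084/m9.figshare.28916828"

REQUIRED_MAPPING_KEYS = ("cell_line", "substrate", "feature", "cell_id", "value")


def apply_column_mapping(df: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Rename deposited-table columns into the measurement schema.

    ``mapping`` maps schema column -> deposited column name; every schema
    column must be covered.
    """
    missing = [k for k in REQUIRED_MAPPING_KEYS if k not in mapping]
    if missing:
        raise MappingError(f"mapping file missing required columns: {missing}")
    absent = [v for v in mapping.values() if v not in df.columns]
    if absent:
        raise MappingError(f"mapped source columns absent from table: {absent}")
    return df.rename(columns={v: k for k, v in mapping.items()})[list(REQUIRED_MAPPING_KEYS)]


def fetch_study_data(url: str, dest: str | Path, timeout: float = 30.0) -> Path:
    """Download one file of the deposited dataset (network required).

    Offline environments get a clean :class:`FetchError`; the rest of the
    pipeline is unaffected.
    """
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            dest.write_bytes(resp.read())
    except Exception as exc:  # noqa: BLE001
        raise FetchError(f"could not fetch {url}: {exc}") from exc
    return dest
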