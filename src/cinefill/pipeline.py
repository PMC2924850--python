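"""End-to-end runs: generate -> (rasterize/segment) -> index -> classify -> report.

A run directory is self-describing: it contains the cohort files, the
per-patient index table, the diagnostic report (text + JSON), and a manifest
recording the seed, configuration hash, package version and per-stage
timings, so re-running from the manifest reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .classify import Thresholds, aggregate_criterion, build_report, classify_cmr, grade_echo
from .cohort import Cohort, CohortSpec, DEFAULT_COUNTS, generate_cohort
from .curve import read_curve_file
from .errors import CinefillError
from .indices import compute_indices
from .phantom import CineGeometry, rasterize_stack, segment_stack
from .report import render_performance_table

logger = logging.getLogger("cinefill")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    n_phases: int = 30
    noise_sd: float = 2.0
    seed: int = 0
    n_harmonics: int | None = None  # None -> adaptive cutoff
    thresholds: Thresholds = field(default_factory=Thresholds)
    use_phantom: bool = False
    geometry: CineGeometry = field(default_factory=CineGeometry)
    curves_dir: str | None = None  # skip generation, read curve files

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "thresholds" in data and isinstance(data["thresholds"], Mapping):
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "geometry" in data and isinstance(data["geometry"], Mapping):
            data["geometry"] = CineGeometry(**data["geometry"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["counts"] = dict(self.counts)
        return out


def indices_for_cohort(
    cohort: Cohort,
    n_harmonics: int | None = None,
    use_phantom: bool = False,
    geometry: CineGeometry | None = None,
) -> pd.DataFrame:
    """Index table (one row per patient) for a generated cohort.

    With ``use_phantom`` the analysis chain runs through rasterisation and
    stand-in segmentation instead of the directly sampled curves.
    """
    rows = []
    for p in cohort:
        curve = p.curve
        if use_phantom:
            stack = rasterize_stack(p.truth, geometry, n_phases=curve.n_phases)
            curve = segment_stack(stack).to_curve()
        idx = compute_indices(curve, n_harmonics=n_harmonics)
        row = {"patient_id": p.patient_id, "grade": p.grade}
        row.update(idx.to_dict())
        row["echo_grade"] = grade_echo(p.echo)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into a run directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    try:
        t0 = time.perf_counter()
        if config.curves_dir is not None:
            curves = {
                path.stem: read_curve_file(path)
                for path in sorted(Path(config.curves_dir).glob("*.csv"))
            }
            logger.info("loaded %d curve files from %s", len(curves), config.curves_dir)
            rows = []
            for pid, curve in curves.items():
                idx = compute_indices(curve, n_harmonics=config.n_harmonics)
                rows.append({"patient_id": pid, **idx.to_dict()})
            index_table = pd.DataFrame(rows)
            cohort = None
        else:
            spec = CohortSpec(
                counts=config.counts,
                n_phases=config.n_phases,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            cohort = generate_cohort(spec)
            cohort.write(out / "cohort")
            timings["generate"] = time.perf_counter() - t0
            logger.info("generated %d patients", len(cohort))

            t0 = time.perf_counter()
            index_table = indices_for_cohort(
                cohort,
                n_harmonics=config.n_harmonics,
                use_phantom=config.use_phantom,
                geometry=config.geometry,
            )
        timings["indices"] = time.perf_counter() - t0
        index_table.to_csv(out / "indices.csv", index=False)
        index_table.to_json(out / "indices.json", orient="records", indent=2)

        if cohort is not None:
            t0 = time.perf_counter()
            grades = [p.grade for p in cohort]
            report = build_report(index_table, grades, config.thresholds)
            report.entries.to_csv(out / "diagnostic_report.csv", index=False)
            report.entries.to_json(out / "diagnostic_report.json", orient="records", indent=2)
            (out / "diagnostic_report.txt").write_text(
                render_performance_table(report) + "\n"
            )
            flags = [
                aggregate_criterion(
                    classify_cmr(_Row(r), config.thresholds)
                )
                for r in index_table.itertuples()
            ]
            index_table = index_table.assign(aggregate_abnormal=flags)
            index_table.to_csv(out / "indices.csv", index=False)
            timings["classify"] = time.perf_counter() - t0

        config_dict = config.to_dict()
        config_hash = hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config_dict,
            "config_sha256": config_hash,
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        marker.unlink()
    except Exception as exc:  # leave the marker so the run is visibly partial
        logger.error("run failed: %s", exc)
        marker.write_text(f"run failed: {exc}\n")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


class _Row:
    """Adapter exposing index-table columns under attribute names."""

    def __init__(self, row):
        self.dvr = row.dvr80_pct
        self.tpfr_ms = row.tpfr_ms
        self.pfr = row.pfr_ml_s
        self.npfr = row.npfr_per_s


def load_manifest(run_dir: str | Path) -> dict:
    return json.loads((Path(run_dir) / "manifest.json").read_text())
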