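"""Reproducible end-to-end runs: config → tables → manifest.

A :class:`RunConfig` names exactly one input source (a synthetic spec, a
line listing, or an aggregate table), the target and comparator drugs, the
evaluated conditions and the analysis parameters.  :func:`run` executes
the stages that apply, writes every output as CSV plus a machine-readable
JSON manifest, and is deterministic: identical config + seed produce
byte-identical outputs.

Stage outputs on disk (all under ``out_dir``):

* ``line_listing.csv``   — generated reactions (simulate stage)
* ``aggregates.csv``     — per-drug long-form counts (aggregate stage)
* ``descriptives.csv``   — summary statistics per drug (describe stage)
* ``pt_distribution.csv``— per-PT counts per drug × condition (describe)
* ``signals_<target>.csv`` — ROR panel per target drug (dispro stage)
* ``manifest.json``      — inputs, seed, versions, row counts, dictionary
  checksum, completed stages
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .descriptives import descriptive_report, pt_distribution
from .disproportionality import DisproportionalityModel
from .errors import PvDisproError, UsageError
from .io import (
    DrugAggregate,
    ICSRDataset,
    aggregate,
    read_aggregate_table,
    read_line_listing,
    write_aggregate_table,
    write_line_listing,
)
from .meddra import Condition, builtin_dictionary, dictionary_checksum
from .simulate import SyntheticSpec, generate, reference_study_spec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "REFERENCE_SPEC_NAME"]

#: Config value selecting the packaged reference study spec instead of a file.
REFERENCE_SPEC_NAME = "builtin:reference"

STAGES = ("simulate", "aggregate", "describe", "dispro")


class RunConfig(BaseModel):
    """Validated pipeline configuration (JSON-serializable)."""

    synthetic_spec: Optional[str] = None
    line_listing: Optional[str] = None
    aggregate_table: Optional[str] = None
    targets: list[str] = Field(default_factory=list)
    comparators: list[str] = Field(default_factory=list)
    conditions: list[Literal["resistance", "ineffectiveness", "other"]] = Field(
        default_factory=lambda: ["ineffectiveness"]
    )
    min_reports: int = 5
    z: float = 1.96
    out_dir: str = "pvdispro_out"
    seed: Optional[int] = None
    force: bool = False

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        sources = [
            s
            for s in (self.synthetic_spec, self.line_listing, self.aggregate_table)
            if s
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one of synthetic_spec / line_listing / aggregate_table "
                "must be set"
            )
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))


def _load_spec(config: RunConfig) -> SyntheticSpec:
    if config.synthetic_spec == REFERENCE_SPEC_NAME:
        spec = reference_study_spec()
    else:
        spec = SyntheticSpec.from_json(config.synthetic_spec)
    if config.seed is not None:
        spec = spec.model_copy(update={"seed": config.seed})
    return spec


def _output_path(out_dir: Path, name: str, force: bool) -> Path:
    path = out_dir / name
    if path.exists() and not force:
        raise UsageError(
            f"refusing to overwrite {path}; pass force=True (--force) to replace it"
        )
    return path


def run(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages; returns the manifest dictionary.

    A stage that does not apply to the configured input (e.g. ``simulate``
    for a line-listing input) is skipped and recorded as such.  A stage
    failure stops the run; the manifest (written regardless) names the
    failed stage and the error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dictionary = builtin_dictionary()

    manifest: dict = {
        "pvdispro_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "dictionary_sha256": dictionary_checksum(dictionary),
        "stages_completed": [],
        "stages_skipped": [],
        "outputs": {},
        "row_counts": {},
        "failed_stage": None,
        "error": None,
    }

    dataset: Optional[ICSRDataset] = None
    aggs: Optional[list[DrugAggregate]] = None
    conditions = [Condition(c) for c in config.conditions]

    try:
        if "simulate" in stages:
            if config.synthetic_spec:
                spec = _load_spec(config)
                manifest["seed"] = spec.seed
                dataset = generate(spec, dictionary)
                path = _output_path(out_dir, "line_listing.csv", config.force)
                write_line_listing(dataset, path)
                manifest["outputs"]["line_listing"] = str(path)
                manifest["row_counts"]["line_listing"] = len(dataset)
                manifest["stages_completed"].append("simulate")
                logger.info("simulate: wrote %d reactions to %s", len(dataset), path)
            else:
                manifest["stages_skipped"].append("simulate")

        if "aggregate" in stages:
            if dataset is None and config.line_listing:
                dataset = read_line_listing(config.line_listing, dictionary)
            if dataset is not None:
                aggs = aggregate(dataset, dictionary)
            elif config.aggregate_table:
                aggs = read_aggregate_table(config.aggregate_table)
            if aggs is not None:
                path = _output_path(out_dir, "aggregates.csv", config.force)
                write_aggregate_table(aggs, path)
                manifest["outputs"]["aggregates"] = str(path)
                manifest["row_counts"]["drugs"] = len(aggs)
                manifest["stages_completed"].append("aggregate")
                logger.info("aggregate: %d drugs", len(aggs))
            else:
                manifest["stages_skipped"].append("aggregate")

        if "describe" in stages:
            if aggs is None:
                raise UsageError("describe stage needs the aggregate stage first")
            path = _output_path(out_dir, "descriptives.csv", config.force)
            descriptive_report(aggs).to_csv(path, index=False, lineterminator="\n")
            manifest["outputs"]["descriptives"] = str(path)
            manifest["stages_completed"].append("describe")
            if dataset is not None:
                rows = []
                for agg in aggs:
                    for cond in (Condition.RESISTANCE, Condition.INEFFECTIVENESS):
                        for pt, n in pt_distribution(
                            dataset, agg.drug, cond, dictionary
                        ).items():
                            rows.append((agg.drug, cond.value, pt, n))
                ptp = _output_path(out_dir, "pt_distribution.csv", config.force)
                pd.DataFrame(
                    rows, columns=["drug", "condition", "pt_name", "count"]
                ).to_csv(ptp, index=False, lineterminator="\n")
                manifest["outputs"]["pt_distribution"] = str(ptp)

        if "dispro" in stages:
            if aggs is None:
                raise UsageError("dispro stage needs the aggregate stage first")
            if not config.targets or not config.comparators:
                raise UsageError(
                    "dispro stage needs non-empty targets and comparators"
                )
            for target in config.targets:
                comparators = [
                    c for c in config.comparators if c.lower() != target.lower()
                ]
                model = DisproportionalityModel(aggs, target, comparators, conditions)
                res = model.fit(z=config.z, min_reports=config.min_reports)
                name = f"signals_{target.lower().replace('/', '_')}.csv"
                path = _output_path(out_dir, name, config.force)
                res.to_csv(path)
                manifest["outputs"][f"signals:{target.lower()}"] = str(path)
                manifest["row_counts"][f"signals:{target.lower()}"] = len(res)
            manifest["stages_completed"].append("dispro")
    except PvDisproError as exc:
        pending = [s for s in stages if s not in manifest["stages_completed"]]
        manifest["failed_stage"] = pending[0] if pending else None
        manifest["error"] = str(exc)
        _write_manifest(out_dir, manifest)
        raise
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
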