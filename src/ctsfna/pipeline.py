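"""End-to-end pipeline: simulate or load a cohort, segment, classify,
panel-vote, and compute diagnostic accuracy, with reproducible outputs.

A run directory receives the effective config snapshot, the cohort truth
table, per-slide cell tables and calls, the reader vote table and the
metrics JSON; rerunning with the same config and seed reproduces all
non-image outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ctsfna.classify import (
    CtsThresholds,
    categorize_slide,
    category_to_call,
    cluster_red_cells,
)
from ctsfna.diagnostics import (
    SlideOutcome,
    confusion,
    intensity_contrast,
    outcomes_from_frame,
    per_category_accuracy,
)
from ctsfna.images import (
    InputError,
    SmearImage,
    assemble_cells,
    cells_to_frame,
    segment_nuclei,
    segment_red,
    write_smear,
)
from ctsfna.readers import ReaderModel, default_panel, majority_vote, read_slide
from ctsfna.simulate import SmearSimConfig, generate_cohort

logger = logging.getLogger("ctsfna")


@dataclass
class CohortSpec:
    """Cohort composition; the default mirrors the study cohort."""

    n_malignant: int = 63
    n_benign: int = 30
    n_normal: int = 33


@dataclass
class PanelSpec:
    n_readers: int = 3
    threshold_jitter: float = 0.05
    flip_prob: float = 0.02


@dataclass
class PipelineConfig:
    """Full pipeline configuration (YAML-serializable)."""

    seed: int = 0
    log_level: str = "INFO"
    write_images: bool = False
    outcomes_csv: str | None = None  # replay mode: evaluate an existing table
    cohort: CohortSpec = field(default_factory=CohortSpec)
    simulation: SmearSimConfig = field(default_factory=SmearSimConfig)
    thresholds: CtsThresholds = field(default_factory=CtsThresholds)
    panel: PanelSpec = field(default_factory=PanelSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_type, data, where):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(data) - names
            if unknown:
                raise InputError(
                    f"unknown key(s) {sorted(unknown)} in config section {where!r}"
                )
            return dc_type(**data)

        kwargs = dict(raw)
        for key, dc_type in (
            ("cohort", CohortSpec),
            ("simulation", SmearSimConfig),
            ("thresholds", CtsThresholds),
            ("panel", PanelSpec),
        ):
            if key in kwargs:
                section = kwargs[key]
                if not isinstance(section, dict):
                    raise InputError(f"config section {key!r} must be a mapping")
                # YAML lists become tuples where the dataclass expects them
                for k, v in list(section.items()):
                    if isinstance(v, list):
                        section[k] = tuple(v)
                    elif isinstance(v, dict):
                        section[k] = {
                            kk: tuple(vv) if isinstance(vv, list) else vv
                            for kk, vv in v.items()
                        }
                kwargs[key] = build(dc_type, section, key)
        return build(cls, kwargs, "<root>")

    def to_dict(self) -> dict:
        def listify(x):
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            if isinstance(x, list):
                return [listify(v) for v in x]
            return x

        return listify(dataclasses.asdict(self))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def slide_red_intensity(cells, clusters) -> float:
    """Median red intensity of the slide's dominant aggregate region.

    The largest cluster stands in for the "region of cell aggregation";
    with no clusters the median over red-positive cells is used; 0 if the
    slide has no red signal at all.
    """
    if clusters:
        biggest = max(clusters, key=lambda c: c.size)
        members = {i for i in biggest.member_ids}
        vals = [c.median_red for c in cells if c.cell_id in members]
        return float(np.median(vals)) if vals else 0.0
    vals = [c.median_red for c in cells if c.red_positive]
    return float(np.median(vals)) if vals else 0.0


def process_slide(image: SmearImage, thresholds: CtsThresholds | None = None) -> dict:
    """Segment, measure and categorize one smear image."""
    thresholds = thresholds or CtsThresholds()
    nuclei = segment_nuclei(image)
    red_mask = segment_red(image)
    cells = assemble_cells(
        nuclei,
        red_mask,
        image,
        enlargement_um=thresholds.enlargement_um,
        circularity_irregular=thresholds.circularity_irregular,
    )
    clusters = cluster_red_cells(cells, thresholds)
    category = categorize_slide(cells, clusters, thresholds)
    return {
        "cells": cells,
        "clusters": clusters,
        "category": category,
        "call": category_to_call(category),
        "red_intensity": slide_red_intensity(cells, clusters),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the configured pipeline end to end; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    from ctsfna import __version__  # deferred: avoids a circular import

    log_lines = [f"ctsfna {__version__}", f"seed {config.seed}"]

    (out / "config.yaml").write_text(config.to_yaml())

    if config.outcomes_csv:
        frame = pd.read_csv(config.outcomes_csv)
        errors = validate_cohort_csv(config.outcomes_csv)
        if errors:
            raise InputError(f"invalid outcomes CSV: {errors}")
        outcomes = outcomes_from_frame(frame)
        metrics = {"index": confusion(outcomes).as_dict()}
        if frame.get("comparator_call") is not None and frame["comparator_call"].notna().any():
            metrics["comparator"] = confusion(outcomes, use_comparator=True).as_dict()
        _write_metrics(out, metrics, log_lines)
        return out

    sim = replace(config.simulation, seed=config.seed)
    cohort, slides = generate_cohort(
        config.cohort.n_malignant,
        config.cohort.n_benign,
        config.cohort.n_normal,
        base_config=sim,
        seed=config.seed,
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    readers = default_panel(
        seed=config.seed,
        n_readers=config.panel.n_readers,
        threshold_jitter=config.panel.threshold_jitter,
        flip_prob=config.panel.flip_prob,
    )

    cell_frames = []
    vote_rows = []
    call_rows = []
    outcomes = []
    categories = []
    for row, (image, truth) in zip(cohort.itertuples(), slides):
        res = process_slide(image, config.thresholds)
        cell_frames.append(cells_to_frame(res["cells"], slide_id=row.slide_id))
        calls = [
            read_slide(res["cells"], r, row.slide_id, config.thresholds)
            for r in readers
        ]
        panel = majority_vote(calls)
        for r, call in zip(readers, calls):
            vote_rows.append(
                {
                    "slide_id": row.slide_id,
                    "reader_id": r.reader_id,
                    "call": call,
                    "consensus": panel.consensus,
                }
            )
        call_rows.append(
            {
                "slide_id": row.slide_id,
                "category": res["category"].value,
                "call": res["call"],
                "consensus": panel.consensus,
                "rationale": res["category"].rationale,
            }
        )
        categories.append(res["category"].value)
        outcomes.append(
            SlideOutcome(
                slide_id=row.slide_id,
                index_call=panel.consensus,
                reference="malignant" if row.truth_class == "malignant" else "benign_normal",
                red_intensity=res["red_intensity"],
            )
        )
        if config.write_images:
            write_smear(image, out / f"{row.slide_id}.tiff")

    pd.concat(cell_frames, ignore_index=True).to_csv(out / "cells.csv", index=False)
    pd.DataFrame(vote_rows).to_csv(out / "votes.csv", index=False)
    (out / "calls.json").write_text(
        json.dumps(
            {
                "thresholds": dataclasses.asdict(config.thresholds),
                "slides": call_rows,
            },
            sort_keys=True,
            indent=1,
        )
    )
    pd.DataFrame(
        [
            {
                "slide_id": o.slide_id,
                "index_call": o.index_call,
                "reference": o.reference,
                "red_intensity": o.red_intensity,
            }
            for o in outcomes
        ]
    ).to_csv(out / "outcomes.csv", index=False)

    metrics = {
        "index": confusion(outcomes).as_dict(),
        "per_category": per_category_accuracy(
            categories, [o.reference for o in outcomes]
        ).to_dict(orient="records"),
        "intensity": intensity_contrast(outcomes),
    }
    _write_metrics(out, metrics, log_lines)
    return out


def _write_metrics(out: Path, metrics: dict, log_lines: list[str]) -> None:
    (out / "metrics.json").write_text(json.dumps(metrics, sort_keys=True, indent=1))
    report = ["# Diagnostic accuracy report", ""]
    for arm, m in metrics.items():
        if arm not in ("index", "comparator"):
            continue
        report.append(f"## {arm} test")
        report.append("")
        report.append("| metric | value |")
        report.append("|---|---|")
        for k in ("tp", "fp", "fn", "tn", "n_inadequate"):
            report.append(f"| {k} | {m[k]} |")
        for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "insufficiency_rate"):
            report.append(f"| {k} (%) | {m[k]} |")
        report.append("")
    (out / "report.md").write_text("\n".join(report) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)


REQUIRED_COLUMNS = ("slide_id", "index_call", "reference")
LEVELS = {
    "index_call": {"positive", "negative", "inadequate"},
    "reference": {"malignant", "benign_normal"},
    "comparator_call": {"malignant_suspicious", "atypical", "benign", "inadequate"},
}


def validate_cohort_csv(path: str | Path) -> list[dict]:
    """Schema check for an outcomes CSV; returns a machine-readable error list."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path)
    errors: list[dict] = []
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            errors.append({"kind": "missing_column", "column": col})
    if "slide_id" in frame.columns:
        dupes = frame["slide_id"][frame["slide_id"].duplicated()].unique().tolist()
        if dupes:
            errors.append({"kind": "duplicate_slide_id", "values": dupes})
    for col, levels in LEVELS.items():
        if col in frame.columns:
            vals = frame[col].dropna().unique()
            bad = sorted(set(map(str, vals)) - levels)
            if bad:
                errors.append({"kind": "unknown_level", "column": col, "values": bad})
    return errors
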