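"""End-to-end run orchestration: quantify -> abundance -> co-labelling.

A run is described by a YAML config listing one image fixture per
case/region plus thresholds, analysis flags and a seed.  ``run_pipeline``
executes every stage, writes all tables and a machine-readable summary
JSON, and logs every threshold and decision flag so each number in the
summary is traceable to its config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, colabel, quantify
from .io import read_background_points, read_cases, read_cells, read_image, write_cells

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Validated run description.

    ``images`` is a list of dicts with keys ``case_id``, ``region``,
    ``tiff``, ``cells``, ``background``.
    """

    images: list[dict]
    output_dir: str
    cases_csv: str | None = None
    iba1_threshold: float = 20.0
    marker_thresholds: dict = dataclasses.field(
        default_factory=lambda: {"hla_dr": 20.0, "moi": 20.0}
    )
    t_high: dict = dataclasses.field(
        default_factory=lambda: {"hla_dr": 40.0, "moi": 40.0}
    )
    per_case: bool = False
    yates: bool = False
    welch: bool = False
    exclude_saturated: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.images:
            raise ValueError("config lists no images")
        for entry in self.images:
            for key in ("case_id", "region", "tiff", "cells", "background"):
                if key not in entry:
                    raise ValueError(f"image entry missing key {key!r}: {entry}")
            for key in ("tiff", "cells", "background"):
                if not Path(entry[key]).exists():
                    raise FileNotFoundError(
                        f"{key} file not found for case "
                        f"{entry['case_id']}: {entry[key]}"
                    )
            sidecar = Path(entry["tiff"]).with_suffix(".yaml")
            if not sidecar.exists():
                raise FileNotFoundError(f"channel map not found: {sidecar}")
        if self.cases_csv and not Path(self.cases_csv).exists():
            raise FileNotFoundError(f"cases_csv not found: {self.cases_csv}")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def quantify_fixture(entry: dict, config: RunConfig) -> pd.DataFrame:
    """Measure one case/region fixture into an augmented cell table."""
    image = read_image(entry["tiff"])
    cells = read_cells(entry["cells"])
    points = read_background_points(entry["background"])
    backgrounds = {
        ch: quantify.estimate_background(
            image, ch, grp[["row", "col"]].to_numpy()
        )
        for ch, grp in points.groupby("channel")
        if ch != "hoechst"
    }
    measured = quantify.measure_cells(
        image, cells, backgrounds,
        iba1_threshold=config.iba1_threshold,
        marker_thresholds=config.marker_thresholds,
    )
    measured.attrs["backgrounds"] = {
        ch: bg.value for ch, bg in backgrounds.items()
    }
    return measured


def _report_to_jsonable(obj):
    if isinstance(obj, colabel.CorrelationReport):
        return obj.as_dict()
    if isinstance(obj, colabel.FourWayCounts):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _report_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_report_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute quantification, abundance and co-labelling; write a report
    bundle (tables, log, summary JSON) into ``config.output_dir``.

    Deterministic given the config.  Any stage failure aborts with the
    stage name and cause.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("microquant")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config": config.snapshot(), "stages": {}}
    try:
        logger.info("config snapshot: %s", json.dumps(config.snapshot(), default=str))

        # --- stage: quantify -------------------------------------------
        stage = "quantify"
        try:
            measured_all, backgrounds_per_case = [], {}
            for entry in config.images:
                measured = quantify_fixture(entry, config)
                backgrounds_per_case[(entry["case_id"], entry["region"])] = (
                    measured.attrs["backgrounds"]
                )
                measured_all.append(measured)
            cells = pd.concat(measured_all, ignore_index=True)
            write_cells(cells, out / "cells_quantified.csv")
            summary["stages"][stage] = {
                "n_cells": len(cells),
                "n_iba1_positive": int(cells["iba1_positive"].sum()),
                "backgrounds": {
                    f"{c}/{r}": bg for (c, r), bg in backgrounds_per_case.items()
                },
            }
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # --- stage: abundance ------------------------------------------
        stage = "abundance"
        try:
            fractions = pd.concat(
                [abundance.positive_fraction(cells, m) for m in ("hla_dr", "moi")],
                ignore_index=True,
            )
            fractions.to_csv(out / "fractions.csv", index=False)
            abundance_summary: dict = {"fractions": _report_to_jsonable(fractions)}
            complete = (
                fractions.pivot_table(
                    index="case_id", columns="region", values="percent"
                )
                .notna()
                .all(axis=1)
                .sum()
            )
            if {"GM", "WM"} <= set(cells["region"]) and complete >= 2:
                for marker in ("hla_dr", "moi"):
                    abundance_summary[f"gm_wm_{marker}"] = _report_to_jsonable(
                        abundance.compare_gm_wm(
                            fractions[fractions["marker"] == marker]
                        )
                    )
            else:
                logger.info("GM/WM paired comparison skipped: fewer than 2 "
                            "cases with both regions")
            if config.cases_csv:
                cases = read_cases(config.cases_csv)
                abundance_summary["demographics"] = _report_to_jsonable(
                    abundance.summarize_cases(cases).reset_index()
                )
                for marker in ("hla_dr", "moi"):
                    abundance_summary[f"demographic_corr_{marker}"] = (
                        _report_to_jsonable(
                            abundance.correlate_demographics(
                                fractions[fractions["marker"] == marker], cases
                            )
                        )
                    )
            if "morphology" in cells.columns:
                abundance_summary["morphology_crosstab"] = _report_to_jsonable(
                    abundance.morphology_crosstab(cells).reset_index()
                )
            summary["stages"][stage] = abundance_summary
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # --- stage: colabel --------------------------------------------
        stage = "colabel"
        try:
            pooled_bg: dict[str, float] = {}
            for marker in ("hla_dr", "moi"):
                vals = [bg[marker] for bg in backgrounds_per_case.values()]
                pooled_bg[marker] = float(sum(vals) / len(vals))
            thresholds = colabel.HighLowThresholds(
                t_high=dict(config.t_high),
                positivity=dict(config.marker_thresholds),
            )
            iba1_cells = cells[cells["iba1_positive"]]
            analysis_cells = iba1_cells
            if config.exclude_saturated:
                analysis_cells = iba1_cells[
                    (iba1_cells["pi_hla_dr"] < 255) & (iba1_cells["pi_moi"] < 255)
                ]
            categorized = colabel.categorize_highlow(
                analysis_cells, pooled_bg, thresholds
            )
            categorized_out = categorized.copy()
            write_cells(categorized_out, out / "cells_categorized.csv")
            counts = colabel.fourway_counts(categorized)
            colabel_summary = {
                "pearson_pooled": colabel.pearson_pooled(analysis_cells),
                "top10_by_hla": colabel.top_decile_subset(
                    analysis_cells, "hla_dr"
                )[1],
                "top10_by_moi": colabel.top_decile_subset(
                    analysis_cells, "moi"
                )[1],
                "saturation": colabel.saturation_sensitivity(iba1_cells),
                "fourway_counts": counts,
                "chi_square": colabel.chi_square_independence(
                    counts, yates=config.yates
                ),
            }
            if categorized["case_id"].nunique() >= 2:
                colabel_summary["conditional_by_hla"] = (
                    colabel.conditional_proportion_test(
                        categorized, group_by="hla_dr", outcome="moi",
                        welch=config.welch,
                    )
                )
                colabel_summary["conditional_by_moi"] = (
                    colabel.conditional_proportion_test(
                        categorized, group_by="moi", outcome="hla_dr",
                        welch=config.welch,
                    )
                )
            else:
                logger.info("conditional-proportion tests skipped: fewer "
                            "than 2 cases")
            if config.per_case:
                per_case = {}
                for case_id, c in colabel.fourway_by_case(categorized).items():
                    entry = {"counts": c}
                    try:
                        entry["chi_square"] = colabel.chi_square_independence(
                            c, yates=config.yates
                        )
                    except ValueError as exc:
                        entry["chi_square"] = {"error": str(exc)}
                    per_case[case_id] = entry
                colabel_summary["per_case"] = per_case
            summary["stages"][stage] = _report_to_jsonable(colabel_summary)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        with open(out / "summary.json", "w") as fh:
            json.dump(_report_to_jsonable(summary), fh, indent=2, sort_keys=True)
        logger.info("run complete: %s", out / "summary.json")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
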