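"""Full-pipeline orchestration: ingest -> metrics -> tables -> fits -> report.

The pipeline is a pure function of its input files and configuration:
rerunning on identical inputs produces identical outputs (the JSON report
carries no timestamps).  Stage-level logging records how many webs each
filter drops, since the filters silently reshape the dataset otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .biomass_pipeline import (
    PipelineConfig,
    build_across_table,
    build_within_table,
)
from .foodweb_io import FoodWeb, read_web_tables
from .scaling_models import (
    ModelFitError,
    ScalingFit,
    fit_across_ancova,
    fit_per_web_ols,
    fit_prey_mass_model,
    fit_trait_lme,
    fit_within_lme,
)
from .trophic_metrics import metrics_table

logger = logging.getLogger("trophoscale")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_EMPTY = 3


class EmptyResultError(RuntimeError):
    """Every web was removed by the filters; there is nothing to fit."""


@dataclass
class PipelineReport:
    """Record of one pipeline run: per-stage counts, fits and config echo."""

    config: dict
    version: str = __version__
    counts: dict[str, int] = field(default_factory=dict)
    fits: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def pipeline_config_from_mapping(raw: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from (a section of) a config mapping,
    ignoring unknown keys with a warning."""
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        logger.warning("ignoring unknown filter config keys: %s", sorted(unknown))
    return PipelineConfig(**{k: v for k, v in raw.items() if k in known})


def run_pipeline(
    nodes_csv: str | Path,
    links_csv: str | Path,
    config: Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Execute every analysis stage in order and return the report.

    ``config`` sections: ``filtering`` (see :class:`PipelineConfig`),
    ``models`` (``alpha``, ``prey_mass_outliers``), ``io``
    (``column_mapping``).  If ``out_dir`` is given, intermediate CSVs and
    ``report.json`` are written there.
    """
    config = dict(config or {})
    pcfg = pipeline_config_from_mapping(config.get("filtering"))
    mcfg = dict(config.get("models") or {})
    webs = read_web_tables(
        nodes_csv, links_csv, column_mapping=config.get("io")
    )
    return run_pipeline_on_webs(webs, pcfg, mcfg, config_echo=config, out_dir=out_dir)


def run_pipeline_on_webs(
    webs: list[FoodWeb],
    pcfg: PipelineConfig,
    mcfg: Mapping[str, Any] | None = None,
    config_echo: Mapping[str, Any] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Pipeline body operating on already-loaded webs."""
    mcfg = dict(mcfg or {})
    alpha = float(mcfg.get("alpha", 0.05))
    outliers = list(mcfg.get("prey_mass_outliers", []))
    report = PipelineReport(config=dict(config_echo or {}))
    report.counts["webs_input"] = len(webs)

    metrics = metrics_table(webs)
    within = build_within_table(webs, pcfg)
    across = build_across_table(webs, pcfg)
    report.counts["webs_within"] = int(within["web_id"].nunique()) if len(within) else 0
    report.counts["webs_across"] = int(len(across))
    report.counts["predator_records"] = int(len(within))

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False)
        within.to_csv(out / "within_table.csv", index=False)
        across.to_csv(out / "across_table.csv", index=False)

    if report.counts["webs_within"] == 0 and report.counts["webs_across"] == 0:
        if out is not None:
            report.to_json(out / "report.json")
        raise EmptyResultError("no webs survive the filters")

    def _try(name: str, fn):
        try:
            return fn()
        except (ModelFitError, ValueError) as exc:
            msg = f"{name}: {exc}"
            logger.warning(msg)
            report.warnings.append(msg)
            return None

    if report.counts["webs_within"] >= 2:
        fit_w = _try("fit_within", lambda: fit_within_lme(within, alpha=alpha))
        if fit_w is not None:
            report.fits["within"] = fit_w.to_dict()
        trait_res = _try("fit_traits", lambda: fit_trait_lme(within, alpha=alpha))
        if trait_res is not None:
            fit_t, partial = trait_res
            report.fits["traits"] = fit_t.to_dict()
            if out is not None and len(partial):
                partial.to_csv(out / "partial_residuals.csv", index=False)
        slopes = fit_per_web_ols(within)
        report.counts["per_web_slopes"] = int(len(slopes))
        if out is not None:
            slopes.to_csv(out / "per_web_slopes.csv", index=False)

    if len(across) >= 3:
        fit_a = _try("fit_across", lambda: fit_across_ancova(across))
        if fit_a is not None:
            report.fits["across"] = fit_a.to_dict()
        fit_m = _try(
            "fit_prey_mass", lambda: fit_prey_mass_model(across, outliers)
        )
        if fit_m is not None:
            report.fits["prey_mass"] = fit_m.to_dict()

    if out is not None:
        report.to_json(out / "report.json")
    return report


def summarize_report(report: PipelineReport | Mapping[str, Any]) -> str:
    """Human-readable one-screen summary of a pipeline report."""
    if isinstance(report, PipelineReport):
        data = dataclasses.asdict(report)
    else:
        data = dict(report)
    lines = [f"trophoscale {data.get('version', '?')} pipeline report"]
    counts = data.get("counts", {})
    lines.append(
        "  webs: {in_} in, {w} within-web, {a} across-web; "
        "{p} predator records".format(
            in_=counts.get("webs_input", "?"),
            w=counts.get("webs_within", "?"),
            a=counts.get("webs_across", "?"),
            p=counts.get("predator_records", "?"),
        )
    )
    for name, fit in data.get("fits", {}).items():
        ci = fit.get("ci_k", (float("nan"), float("nan")))
        lines.append(
            f"  {name}: k_bar = {fit.get('k_bar', float('nan')):.3f} "
            f"(95% CI {ci[0]:.3f} to {ci[1]:.3f}), "
            f"n = {fit.get('n_records', '?')}"
        )
    for w in data.get("warnings", []):
        lines.append(f"  warning: {w}")
    return "\n".join(lines)
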