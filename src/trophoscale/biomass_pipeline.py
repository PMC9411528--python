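"""From webs + metrics to the two analysis tables.

Within-web analysis: one row per retained predator, pairing its standing
biomass (abundance x body mass, g/m^2) with the total biomass of its prey,
each prey's biomass shared equally among its consumers (divided by its
vulnerability).  Across-web analysis: one row per web with total predator and
total prey biomass plus mean prey body mass.

Filters mirror the study design: predators must have a prey-averaged trophic
level above a cutoff (default 2.5); webs are retained only with at least five
such predators and at least one decade of spread in the prey-biomass
covariate.  Predators aggregated to coarse taxonomic groupings are excluded
from the within-web table but kept in the across-web totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .foodweb_io import FoodWeb, TaxonNode
from .trophic_metrics import TrophicMetrics, compute_metrics

logger = logging.getLogger("trophoscale")

WITHIN_COLUMNS = [
    "web_id",
    "ecosystem_type",
    "predator_id",
    "taxon_name",
    "log10_prey_biomass",
    "log10_predator_biomass",
    "ppmr_log10",
    "omnivory",
    "trophic_level",
]
ACROSS_COLUMNS = [
    "web_id",
    "ecosystem_type",
    "log10_total_predator_biomass",
    "log10_total_prey_biomass",
    "log10_mean_prey_mass",
    "n_predators",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Filtering and aggregation switches.

    tl_cutoff:
        minimum prey-averaged trophic level for a node to count as a
        predator (strict inequality).  3.0 is the standard sensitivity
        setting.
    adjust_vulnerability:
        divide each prey's biomass by its number of consumers before
        summing availability (the main analysis); False gives the
        unadjusted sensitivity variant.
    min_predators / min_x_range_decades:
        web-retention thresholds on the within-web records.
    exclude_aggregates_within:
        drop coarse taxonomic groupings from the within-web table (they
        always remain in across-web totals).
    share_prey_across / weight_prey_mass_by_abundance:
        across-web variants: share prey biomass by vulnerability in the
        web totals, and abundance-weight the mean prey body mass.
    """

    tl_cutoff: float = 2.5
    adjust_vulnerability: bool = True
    min_predators: int = 5
    min_x_range_decades: float = 1.0
    exclude_aggregates_within: bool = True
    share_prey_across: bool = False
    weight_prey_mass_by_abundance: bool = False


DEFAULT_CONFIG = PipelineConfig()


def node_biomass(node: TaxonNode) -> float:
    """Standing biomass of a node: abundance (per m^2) x body mass (g)."""
    return node.abundance * node.body_mass


def available_prey_biomass(
    web: FoodWeb, predator_id: str, adjust_for_vulnerability: bool = True
) -> float:
    """Total biomass of a predator's prey, in g/m^2.

    With adjustment, each prey contributes ``biomass / vulnerability`` so
    that a prey shared by several predators is split equally among them.
    """
    node = web._node_map
    total = 0.0
    for p in web.prey_of(predator_id):
        b = node_biomass(node[p])
        if adjust_for_vulnerability:
            v = len(web.consumers_of(p))
            assert v >= 1, f"prey {p} has vulnerability 0 yet is consumed"
            b /= v
        total += b
    return total


def filter_predators(
    web: FoodWeb,
    metrics: Mapping[str, TrophicMetrics],
    tl_cutoff: float = 2.5,
    exclude_aggregates: bool = False,
) -> set[str]:
    """Ids of nodes qualifying as predators: trophic level strictly above the
    cutoff, optionally dropping aggregate nodes (within-web use)."""
    out = set()
    for n in web.nodes:
        m = metrics[n.node_id]
        if m.trophic_level <= tl_cutoff:
            continue
        if exclude_aggregates and n.is_aggregate:
            continue
        out.add(n.node_id)
    return out


def filter_webs(
    records: pd.DataFrame,
    min_predators: int = 5,
    min_x_range_decades: float = 1.0,
) -> set[str]:
    """Web ids whose record group has enough predators and enough spread in
    the (log10) prey-biomass covariate."""
    keep = set()
    for web_id, grp in records.groupby("web_id", sort=False):
        if len(grp) < min_predators:
            continue
        x = grp["log10_prey_biomass"]
        if x.max() - x.min() < min_x_range_decades:
            continue
        keep.add(str(web_id))
    return keep


def _predator_records(
    web: FoodWeb,
    metrics: Mapping[str, TrophicMetrics],
    config: PipelineConfig,
) -> list[dict]:
    predators = filter_predators(
        web,
        metrics,
        tl_cutoff=config.tl_cutoff,
        exclude_aggregates=config.exclude_aggregates_within,
    )
    node = web._node_map
    rows = []
    n_nonpositive = 0
    for pid in sorted(predators):
        y = node_biomass(node[pid])
        x = available_prey_biomass(
            web, pid, adjust_for_vulnerability=config.adjust_vulnerability
        )
        if y <= 0 or x <= 0:
            n_nonpositive += 1
            continue
        m = metrics[pid]
        rows.append(
            {
                "web_id": web.web_id,
                "ecosystem_type": web.ecosystem_type,
                "predator_id": pid,
                "taxon_name": node[pid].taxon_name,
                "log10_prey_biomass": float(np.log10(x)),
                "log10_predator_biomass": float(np.log10(y)),
                "ppmr_log10": m.ppmr_log10,
                "omnivory": m.omnivory,
                "trophic_level": m.trophic_level,
            }
        )
    if n_nonpositive:
        logger.info(
            "web %s: dropped %d predator(s) with non-positive biomass on "
            "either axis",
            web.web_id,
            n_nonpositive,
        )
    return rows


def build_within_table(
    webs: Iterable[FoodWeb], config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-predator within-web records for all retained webs.

    Applies the predator trophic-level filter, the aggregate exclusion, the
    log10 transforms, and then the web-retention filter.
    """
    rows: list[dict] = []
    for web in webs:
        metrics = compute_metrics(web)
        rows.extend(_predator_records(web, metrics, config))
    table = pd.DataFrame(rows, columns=WITHIN_COLUMNS)
    if table.empty:
        return table
    keep = filter_webs(
        table,
        min_predators=config.min_predators,
        min_x_range_decades=config.min_x_range_decades,
    )
    dropped = table.loc[~table["web_id"].isin(keep), "web_id"].nunique()
    if dropped:
        logger.info("within-web filter: dropped %d web(s)", dropped)
    return table[table["web_id"].isin(keep)].reset_index(drop=True)


def build_across_table(
    webs: Iterable[FoodWeb], config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-web summaries: total predator biomass, total prey biomass, mean
    prey body mass.

    Predators are the trophic-level-filtered set *including* aggregate
    nodes; their prey union is totalled with each prey counted once at full
    biomass (unless ``share_prey_across``).  A node that is both predator
    and prey contributes to both totals.  Webs are retained only if their
    aggregate-inclusive predator records pass the web filter.
    """
    rows: list[dict] = []
    record_rows: list[dict] = []
    for web in webs:
        metrics = compute_metrics(web)
        predators = filter_predators(
            web, metrics, tl_cutoff=config.tl_cutoff, exclude_aggregates=False
        )
        node = web._node_map
        # web filter operates on the aggregate-inclusive predator records
        for pid in sorted(predators):
            y = node_biomass(node[pid])
            x = available_prey_biomass(
                web, pid, adjust_for_vulnerability=config.adjust_vulnerability
            )
            if y > 0 and x > 0:
                record_rows.append(
                    {
                        "web_id": web.web_id,
                        "log10_prey_biomass": float(np.log10(x)),
                    }
                )
        prey_union = sorted(
            {p for pid in predators for p in web.prey_of(pid)}
        )
        if not predators or not prey_union:
            logger.info(
                "web %s: empty predator or prey set, excluded from "
                "across-web table",
                web.web_id,
            )
            continue
        total_pred = sum(node_biomass(node[pid]) for pid in predators)
        if config.share_prey_across:
            total_prey = sum(
                node_biomass(node[p]) / len(web.consumers_of(p))
                for p in prey_union
            )
        else:
            total_prey = sum(node_biomass(node[p]) for p in prey_union)
        masses = np.array([node[p].body_mass for p in prey_union])
        if config.weight_prey_mass_by_abundance:
            wts = np.array([node[p].abundance for p in prey_union])
            mean_mass = float(np.average(masses, weights=wts)) if wts.sum() else np.nan
        else:
            mean_mass = float(masses.mean())
        if total_pred <= 0 or total_prey <= 0:
            logger.info(
                "web %s: non-positive totals, excluded from across-web table",
                web.web_id,
            )
            continue
        rows.append(
            {
                "web_id": web.web_id,
                "ecosystem_type": web.ecosystem_type,
                "log10_total_predator_biomass": float(np.log10(total_pred)),
                "log10_total_prey_biomass": float(np.log10(total_prey)),
                "log10_mean_prey_mass": float(np.log10(mean_mass)),
                "n_predators": len(predators),
            }
        )
    table = pd.DataFrame(rows, columns=ACROSS_COLUMNS)
    if table.empty:
        return table
    records = pd.DataFrame(record_rows, columns=["web_id", "log10_prey_biomass"])
    keep = filter_webs(
        records,
        min_predators=config.min_predators,
        min_x_range_decades=config.min_x_range_decades,
    )
    dropped = table.loc[~table["web_id"].isin(keep), "web_id"].nunique()
    if dropped:
        logger.info("across-web filter: dropped %d web(s)", dropped)
    return table[table["web_id"].isin(keep)].reset_index(drop=True)
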