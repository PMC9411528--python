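"""Biomass computation, vulnerability sharing, filters and analysis tables."""

import numpy as np
import pandas as pd
import pytest

from trophoscale import (
    FoodWeb,
    PipelineConfig,
    TaxonNode,
    available_prey_biomass,
    build_across_table,
    build_within_table,
    compute_metrics,
    filter_predators,
    filter_webs,
    node_biomass,
)
from conftest import make_web, random_dag_web


def test_node_biomass_is_abundance_times_mass():
    assert node_biomass(TaxonNode("a", "a", 0.5, 10.0)) == 5.0
    assert node_biomass(TaxonNode("a", "a", 0.5, 0.0)) == 0.0


def test_prey_biomass_unshared(chain_web):
    # B's biomass 0.1 * 50 = 5, eaten only by C
    assert available_prey_biomass(chain_web, "C") == pytest.approx(5.0)


def test_prey_biomass_shared_between_two_predators():
    web = make_web(
        "share",
        "marine",
        [("A", 1.0, 4.0), ("P", 1.0, 1.0), ("Q", 1.0, 1.0)],
        [("P", "A"), ("Q", "A")],
    )
    assert available_prey_biomass(web, "P") == pytest.approx(2.0)
    assert available_prey_biomass(web, "P", adjust_for_vulnerability=False) == \
        pytest.approx(4.0)


def test_vulnerability_shares_conserve_biomass():
    """Sum of shares over all predators equals the total consumed biomass."""
    rng = np.random.default_rng(5)
    for i in range(20):
        web = random_dag_web(rng, web_id=f"c{i}")
        consumers = [n.node_id for n in web.nodes if web.prey_of(n.node_id)]
        total_shares = sum(available_prey_biomass(web, c) for c in consumers)
        consumed = {p for c in consumers for p in web.prey_of(c)}
        total_biomass = sum(node_biomass(web.node(p)) for p in consumed)
        assert total_shares == pytest.approx(total_biomass, rel=1e-9)


def test_filter_predators_cutoff_and_monotonicity(chain_web):
    metrics = compute_metrics(chain_web)
    assert filter_predators(chain_web, metrics, tl_cutoff=2.5) == {"C"}
    loose = filter_predators(chain_web, metrics, tl_cutoff=1.5)
    tight = filter_predators(chain_web, metrics, tl_cutoff=3.0)
    assert tight <= loose


def test_filter_predators_drops_aggregates():
    web = make_web(
        "agg",
        "marine",
        [("A", 1.0, 1.0), ("B", 1.0, 1.0), ("C", 1.0, 1.0, True), ("D", 1.0, 1.0)],
        [("B", "A"), ("C", "B"), ("D", "B")],
    )
    metrics = compute_metrics(web)
    assert filter_predators(web, metrics, 2.5, exclude_aggregates=True) == {"D"}
    assert filter_predators(web, metrics, 2.5, exclude_aggregates=False) == {"C", "D"}


def _records(web_sizes_ranges):
    rows = []
    for wid, (n, span) in web_sizes_ranges.items():
        for i in range(n):
            rows.append(
                {"web_id": wid, "log10_prey_biomass": span * i / max(n - 1, 1)}
            )
    return pd.DataFrame(rows)


def test_filter_webs_rules_and_idempotence():
    recs = _records({"few": (4, 3.0), "narrow": (6, 0.5), "good": (6, 2.0)})
    keep = filter_webs(recs)
    assert keep == {"good"}
    again = filter_webs(recs[recs.web_id.isin(keep)])
    assert again == keep


def test_within_table_applies_all_filters(small_dataset):
    webs, _, _ = small_dataset
    table = build_within_table(webs)
    assert (table["trophic_level"] > 2.5).all()
    counts = table.groupby("web_id").size()
    assert (counts >= 5).all()
    spans = table.groupby("web_id")["log10_prey_biomass"].agg(np.ptp)
    assert (spans >= 1.0).all()
    # brute-force check of the surviving predator set on one web
    web = webs[0]
    if web.web_id in set(table["web_id"]):
        metrics = compute_metrics(web)
        expect = {
            nid for nid, m in metrics.items()
            if m.trophic_level > 2.5 and not web.node(nid).is_aggregate
        }
        got = set(table.loc[table.web_id == web.web_id, "predator_id"])
        assert got <= expect  # only positive-biomass subset retained


def test_across_table_totals_single_predator(chain_web):
    cfg = PipelineConfig(min_predators=1, min_x_range_decades=0.0)
    table = build_across_table([chain_web], cfg)
    assert len(table) == 1
    row = table.iloc[0]
    # C (biomass 10) is the only TL>2.5 predator; its prey is B (biomass 5)
    assert 10 ** row.log10_total_predator_biomass == pytest.approx(10.0)
    assert 10 ** row.log10_total_prey_biomass == pytest.approx(5.0)
    assert 10 ** row.log10_mean_prey_mass == pytest.approx(0.1)
    assert row.n_predators == 1


def test_across_table_node_in_both_roles():
    # D eats C eats B eats A; C is both a predator (TL 3) and prey of D
    web = make_web(
        "both",
        "terrestrial",
        [("A", 1.0, 8.0), ("B", 1.0, 4.0), ("C", 1.0, 2.0), ("D", 1.0, 1.0)],
        [("B", "A"), ("C", "B"), ("D", "C")],
    )
    cfg = PipelineConfig(min_predators=1, min_x_range_decades=0.0)
    row = build_across_table([web], cfg).iloc[0]
    assert 10 ** row.log10_total_predator_biomass == pytest.approx(2.0 + 1.0)
    assert 10 ** row.log10_total_prey_biomass == pytest.approx(4.0 + 2.0)


def test_across_table_includes_aggregates(small_dataset):
    webs, _, _ = small_dataset
    # flag one qualifying predator as an aggregate; across keeps it, within drops it
    base = build_across_table(webs)
    within = build_within_table(webs)
    some_web = within["web_id"].iloc[0]
    pred = within.loc[within.web_id == some_web, "predator_id"].iloc[0]
    mutated = []
    for w in webs:
        if w.web_id != some_web:
            mutated.append(w)
            continue
        nodes = [
            TaxonNode(n.node_id, n.taxon_name, n.body_mass, n.abundance,
                      n.is_basal, is_aggregate=n.node_id == pred)
            for n in w.nodes
        ]
        mutated.append(FoodWeb(w.web_id, w.ecosystem_type, nodes, w.links))
    within2 = build_within_table(mutated)
    across2 = build_across_table(mutated)
    assert pred not in set(within2.loc[within2.web_id == some_web, "predator_id"])
    a1 = base.loc[base.web_id == some_web].iloc[0]
    a2 = across2.loc[across2.web_id == some_web].iloc[0]
    assert a1.log10_total_predator_biomass == a2.log10_total_predator_biomass


def test_abundance_rescaling_shifts_covariates_exactly(small_dataset):
    """Scaling all abundances by f shifts log10 x and y by log10 f."""
    webs, _, _ = small_dataset
    f = 7.5
    scaled = []
    for w in webs:
        nodes = [
            TaxonNode(n.node_id, n.taxon_name, n.body_mass, n.abundance * f,
                      n.is_basal, n.is_aggregate)
            for n in w.nodes
        ]
        scaled.append(FoodWeb(w.web_id, w.ecosystem_type, nodes, w.links))
    t1 = build_within_table(webs)
    t2 = build_within_table(scaled)
    m = t1.merge(t2, on=["web_id", "predator_id"])
    assert np.allclose(
        m.log10_prey_biomass_y - m.log10_prey_biomass_x, np.log10(f), atol=1e-9
    )
    assert np.allclose(
        m.log10_predator_biomass_y - m.log10_predator_biomass_x,
        np.log10(f),
        atol=1e-9,
    )
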