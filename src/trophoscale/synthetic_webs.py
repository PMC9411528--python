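"""Synthetic food-web generator with known scaling parameters.

Webs are built in three steps.  (1) A layered, niche-ordered topology:
basal resources in layer 0, consumers split over higher layers, each
consumer feeding on 1..G nodes from strictly lower layers with a bias
toward the layer immediately below (which yields omnivorous, non-integer
trophic levels while guaranteeing at least three trophic layers).  (2) Body
masses that climb ``ppmr_target_log10`` decades per trophic level with
lognormal scatter.  (3) Biomasses assigned bottom-up so that every
consumer's biomass follows the power law ``y = 10^(c_i) * x^(k_i) * 10^eps``
exactly on the vulnerability-adjusted available-prey-biomass covariate
``x`` — the same covariate the analysis pipeline reconstructs — with
per-web slope/intercept deviations drawn from a correlated bivariate
normal and lognormal residual noise.  Parameter recovery by the fitting
machinery is therefore a sharp test, not an approximation.

Numerical abundance is derived as biomass / body mass, so re-ingesting the
written tables reproduces the generating biomasses exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .biomass_pipeline import available_prey_biomass
from .foodweb_io import (
    ECOSYSTEM_TYPES,
    FoodWeb,
    TaxonNode,
    TrophicLink,
    write_web_tables,
)
from .trophic_metrics import compute_trophic_levels

TRUTH_COLUMNS = ["web_id", "ecosystem_type", "k_i", "c_i", "sigma_res"]


class InfeasibleConfigError(ValueError):
    """The requested topology cannot be built (e.g. all nodes basal, or a
    connectance target out of reach for the layering)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for a synthetic dataset.

    The power-law parameters follow the hierarchical model the within-web
    analysis assumes: per-web slope ``k_i = k_bar_true + eps_k`` and
    intercept ``c_i = c_bar_true + eps_c`` with SDs ``sigma_k``/``sigma_c``
    and correlation ``rho``, plus lognormal residual scatter ``sigma_res``
    (all in log10 units).  ``basal_biomass_range`` (decades of log-uniform
    basal biomass) controls the within-web spread of the prey-biomass
    gradient, while ``web_biomass_gradient_decades`` shifts whole webs along
    a community-biomass gradient (log-uniform per-web offset), emulating
    datasets that span communities from sparse to rich;
    ``ppmr_target_log10`` sets the mean body-size jump per trophic level.
    Trait coefficients default to zero so trait tests have null behaviour
    unless an effect is injected.
    """

    n_webs_per_ecosystem: int = 30
    ecosystem_types: tuple[str, ...] = ECOSYSTEM_TYPES
    species_per_web: tuple[int, int] = (24, 36)
    n_basal: int = 6
    n_layers: int = 4
    connectance_target: float = 0.10
    k_bar_true: float = 0.75
    c_bar_true: float = -0.5
    sigma_k: float = 0.05
    sigma_c: float = 0.3
    rho: float = 0.3
    sigma_res: float = 0.3
    ppmr_effect: float = 0.0
    omnivory_effect: float = 0.0
    basal_biomass_range: float = 4.0
    basal_biomass_center_log10: float = 1.0
    web_biomass_gradient_decades: float = 3.0
    basal_mass_log10: float = -3.0
    mass_scatter_log10: float = 0.6
    ppmr_target_log10: float = 2.0
    prev_layer_weight: float = 2.0
    inject_loops: bool = False
    seed: int = 0


DEFAULT_SYNTHETIC_CONFIG = SyntheticConfig()


@dataclass(frozen=True)
class WebEffects:
    """Realised per-web power-law parameters."""

    k_i: float
    c_i: float


def _species_count(config: SyntheticConfig, rng: np.random.Generator) -> int:
    lo, hi = config.species_per_web
    if lo == hi:
        return int(lo)
    return int(rng.integers(lo, hi + 1))


def _layer_sizes(s: int, config: SyntheticConfig) -> list[int]:
    n_consumers = s - config.n_basal
    n_consumer_layers = config.n_layers - 1
    if config.n_basal < 1:
        raise InfeasibleConfigError("need at least one basal node")
    if config.n_basal >= s:
        raise InfeasibleConfigError(
            f"all {s} nodes basal: no predators possible"
        )
    if n_consumers < n_consumer_layers:
        raise InfeasibleConfigError(
            f"{n_consumers} consumer(s) cannot fill {n_consumer_layers} layers"
        )
    base, extra = divmod(n_consumers, n_consumer_layers)
    sizes = [config.n_basal] + [
        base + (1 if i < extra else 0) for i in range(n_consumer_layers)
    ]
    return sizes


def generate_topology(
    config: SyntheticConfig,
    rng: np.random.Generator,
    web_id: str = "web",
    ecosystem_type: str = "freshwater",
) -> FoodWeb:
    """Build a layered acyclic web skeleton (masses/abundances unset).

    Each consumer samples its prey count from a shifted Poisson whose mean
    targets the requested connectance (links / S^2), drawing prey without
    replacement from lower layers, weighted ``prev_layer_weight : 1`` in
    favour of the immediately lower layer.  With ``inject_loops`` a couple
    of upward links are added to create feeding cycles for stress-testing
    the trophic-level solver.
    """
    s = _species_count(config, rng)
    sizes = _layer_sizes(s, config)
    if not 0 < config.connectance_target < 1:
        raise InfeasibleConfigError("connectance_target must be in (0, 1)")
    layers: list[list[str]] = []
    counter = 0
    for ln, size in enumerate(sizes):
        layers.append([f"{web_id}_n{counter + i}" for i in range(size)])
        counter += size
    nodes = []
    for ln, ids in enumerate(layers):
        for nid in ids:
            nodes.append(
                TaxonNode(
                    node_id=nid,
                    taxon_name=f"taxon_{nid}",
                    body_mass=1.0,
                    abundance=0.0,
                    is_basal=ln == 0,
                    is_aggregate=False,
                )
            )
    n_consumers = s - config.n_basal
    mean_prey = config.connectance_target * s * s / n_consumers
    max_possible = max(sizes[:-1]) + sum(sizes[:-1])  # loose upper bound
    if mean_prey > max_possible:
        raise InfeasibleConfigError(
            f"connectance target {config.connectance_target} needs "
            f"{mean_prey:.1f} prey per consumer on average; not achievable"
        )
    links: list[TrophicLink] = []
    for ln in range(1, len(layers)):
        lower = [(nid, lidx) for lidx in range(ln) for nid in layers[lidx]]
        cand_ids = np.array([nid for nid, _ in lower])
        w = np.array(
            [
                config.prev_layer_weight if lidx == ln - 1 else 1.0
                for _, lidx in lower
            ]
        )
        prev_ids = np.array(layers[ln - 1])
        for nid in layers[ln]:
            g = 1 + rng.poisson(max(mean_prey - 1.0, 0.05))
            g = min(g, len(cand_ids))
            # anchor: one prey from the layer below keeps the web layered
            first = str(rng.choice(prev_ids))
            rest_ids = cand_ids[cand_ids != first]
            w_rest = w[cand_ids != first]
            chosen = [first]
            if g > 1 and len(rest_ids):
                extra = rng.choice(
                    rest_ids,
                    size=min(g - 1, len(rest_ids)),
                    replace=False,
                    p=w_rest / w_rest.sum(),
                )
                chosen.extend(str(e) for e in extra)
            links.extend(TrophicLink(nid, pr) for pr in chosen)
    if config.inject_loops and len(layers) >= 3:
        # a few upward links: lower-layer consumers eating upper-layer nodes
        for _ in range(2):
            src_layer = int(rng.integers(1, len(layers) - 1))
            dst_layer = int(rng.integers(src_layer + 1, len(layers)))
            consumer = str(rng.choice(layers[src_layer]))
            resource = str(rng.choice(layers[dst_layer]))
            if not any(
                l.consumer_id == consumer and l.resource_id == resource
                for l in links
            ):
                links.append(TrophicLink(consumer, resource))
    return FoodWeb(web_id, ecosystem_type, nodes, links)


def assign_biomasses(
    skeleton: FoodWeb,
    web_effects: WebEffects,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> FoodWeb:
    """Fill body masses and abundances so consumer biomass follows the
    generating power law on the vulnerability-adjusted prey-biomass
    covariate.  Requires an acyclic skeleton."""
    tl = compute_trophic_levels(skeleton)
    g = nx.DiGraph()
    g.add_nodes_from(skeleton.node_ids)
    g.add_edges_from(
        (l.resource_id, l.consumer_id)
        for l in skeleton.links
        if not l.is_self_link
    )
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise InfeasibleConfigError(
            f"web {skeleton.web_id!r}: cannot assign biomass bottom-up "
            "(skeleton is not acyclic)"
        ) from exc
    node = skeleton._node_map
    vulnerability = {
        nid: len(skeleton.consumers_of(nid)) for nid in skeleton.node_ids
    }
    masses: dict[str, float] = {}
    for nid in skeleton.node_ids:
        log_m = (
            config.basal_mass_log10
            + config.ppmr_target_log10 * (tl[nid] - 1.0)
            + rng.normal(0.0, config.mass_scatter_log10)
        )
        masses[nid] = 10.0**log_m
    biomass: dict[str, float] = {}
    half = config.basal_biomass_range / 2.0
    ghalf = config.web_biomass_gradient_decades / 2.0
    web_offset = rng.uniform(-ghalf, ghalf) if ghalf > 0 else 0.0
    for nid in order:
        prey = skeleton.prey_of(nid)
        if not prey:
            log_b = (
                config.basal_biomass_center_log10
                + web_offset
                + rng.uniform(-half, half)
            )
            biomass[nid] = 10.0**log_b
            continue
        if any(p not in biomass for p in prey):
            raise InfeasibleConfigError(
                f"web {skeleton.web_id!r}: cannot assign biomass bottom-up "
                "(skeleton is not acyclic)"
            )
        x = sum(biomass[p] / vulnerability[p] for p in prey)
        prey_tls = np.array([tl[p] for p in prey])
        omnivory = float(np.var(prey_tls))
        ppmr_log10 = float(
            np.log10(masses[nid] / np.mean([masses[p] for p in prey]))
        )
        eps = rng.normal(0.0, config.sigma_res) if config.sigma_res > 0 else 0.0
        log_y = (
            web_effects.c_i
            + config.ppmr_effect * (ppmr_log10 - config.ppmr_target_log10)
            + config.omnivory_effect * omnivory
            + web_effects.k_i * np.log10(x)
            + eps
        )
        biomass[nid] = 10.0**log_y
    new_nodes = []
    for n in skeleton.nodes:
        m = masses[n.node_id]
        b = biomass[n.node_id]
        new_nodes.append(
            TaxonNode(
                node_id=n.node_id,
                taxon_name=n.taxon_name,
                body_mass=m,
                abundance=b / m,
                is_basal=n.is_basal,
                is_aggregate=n.is_aggregate,
            )
        )
    return FoodWeb(
        skeleton.web_id, skeleton.ecosystem_type, new_nodes, skeleton.links
    )


def generate_dataset(
    config: SyntheticConfig = DEFAULT_SYNTHETIC_CONFIG,
    out_dir: str | Path | None = None,
) -> tuple[list[FoodWeb], pd.DataFrame]:
    """Generate the full multi-ecosystem dataset plus the truth record.

    Every web draws from its own RNG substream (spawned by counter from the
    config seed), so webs are independent of generation order and identical
    config + seed reproduce the dataset bit-for-bit.  If ``out_dir`` is
    given, writes ``nodes.csv``/``links.csv`` plus ``truth.csv`` with the
    realised per-web parameters.
    """
    webs: list[FoodWeb] = []
    truth_rows = []
    counter = 0
    for eco in config.ecosystem_types:
        for i in range(config.n_webs_per_ecosystem):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(counter,))
            )
            counter += 1
            web_id = f"{eco}_{i:03d}"
            if config.sigma_k > 0 or config.sigma_c > 0:
                cov = np.array(
                    [
                        [
                            config.sigma_c**2,
                            config.rho * config.sigma_c * config.sigma_k,
                        ],
                        [
                            config.rho * config.sigma_c * config.sigma_k,
                            config.sigma_k**2,
                        ],
                    ]
                )
                eps_c, eps_k = rng.multivariate_normal([0.0, 0.0], cov)
            else:
                eps_c = eps_k = 0.0
            effects = WebEffects(
                k_i=config.k_bar_true + eps_k, c_i=config.c_bar_true + eps_c
            )
            skeleton = generate_topology(config, rng, web_id, eco)
            webs.append(assign_biomasses(skeleton, effects, config, rng))
            truth_rows.append(
                {
                    "web_id": web_id,
                    "ecosystem_type": eco,
                    "k_i": effects.k_i,
                    "c_i": effects.c_i,
                    "sigma_res": config.sigma_res,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        write_web_tables(webs, out)
        truth.to_csv(out / "truth.csv", index=False, float_format="%.17g")
    return webs, truth


def realized_connectance(web: FoodWeb) -> float:
    """Links / S^2 (self-links excluded)."""
    s = len(web.nodes)
    if s == 0:
        return 0.0
    n_links = sum(1 for l in web.links if not l.is_self_link)
    return n_links / (s * s)
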