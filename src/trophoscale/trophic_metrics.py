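"""Per-node trophic metrics: trophic level, omnivory, degree, body-mass ratio.

Trophic level follows the prey-averaged convention: ``TL_i = 1 + mean(TL of
prey of i)`` with basal resources fixed at 1 and equal diet weights across a
consumer's prey (interaction strengths are assumed equal).  The defining
system ``TL = 1 + D @ TL`` — ``D`` the row-stochastic diet matrix — is solved
exactly by a linear solve, so webs with feeding loops are handled as long as
every loop can reach a basal resource.

Cannibalistic self-links are excluded from every metric here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .foodweb_io import FoodWeb

logger = logging.getLogger("trophoscale")

METRIC_COLUMNS = [
    "web_id",
    "node_id",
    "trophic_level",
    "omnivory",
    "generality",
    "vulnerability",
    "ppmr_log10",
]


class TrophicLevelError(ValueError):
    """The trophic-level system is singular: a feeding loop has no path to a
    basal resource, so prey-averaged trophic levels are undefined."""


@dataclass(frozen=True)
class TrophicMetrics:
    """All per-node metrics for one node.  ``omnivory`` and ``ppmr_log10``
    are None for nodes without prey (basal resources)."""

    node_id: str
    trophic_level: float
    omnivory: float | None
    generality: int
    vulnerability: int
    ppmr_log10: float | None


def _prey_map(web: FoodWeb) -> dict[str, list[str]]:
    prey: dict[str, list[str]] = {n.node_id: [] for n in web.nodes}
    for l in web.links:
        if not l.is_self_link:
            prey[l.consumer_id].append(l.resource_id)
    return prey


def compute_trophic_levels(web: FoodWeb) -> dict[str, float]:
    """Solve ``(I - D) TL = 1`` for prey-averaged trophic levels.

    ``D[i, p] = 1/generality(i)`` for each prey ``p`` of consumer ``i`` and
    zero on basal rows.  Raises :class:`TrophicLevelError` naming the
    offending strongly connected component when a loop cannot reach a basal
    resource (the system is then singular).
    """
    ids = web.node_ids
    if not ids:
        return {}
    index = {nid: i for i, nid in enumerate(ids)}
    prey = _prey_map(web)
    n = len(ids)
    a = np.eye(n)
    for nid, plist in prey.items():
        if plist:
            w = 1.0 / len(plist)
            i = index[nid]
            for p in plist:
                a[i, index[p]] -= w
    try:
        cond_bad = False
        tl = np.linalg.solve(a, np.ones(n))
        # a numerically singular system can still "solve" with garbage
        if not np.all(np.isfinite(tl)) or np.max(np.abs(a @ tl - 1.0)) > 1e-6:
            cond_bad = True
    except np.linalg.LinAlgError:
        cond_bad = True
    if cond_bad:
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        g.add_edges_from(
            (l.consumer_id, l.resource_id)
            for l in web.links
            if not l.is_self_link
        )
        basal = set(web.basal_ids())
        offenders = [
            sorted(scc)
            for scc in nx.strongly_connected_components(g)
            if len(scc) > 1
            and not any(nx.has_path(g, m, b) for m in scc for b in basal)
        ]
        raise TrophicLevelError(
            f"web {web.web_id!r}: trophic levels undefined; feeding loop(s) "
            f"with no path to a basal resource: {offenders}"
        )
    return {nid: float(tl[index[nid]]) for nid in ids}


def compute_trophic_levels_iterative(
    web: FoodWeb, tol: float = 1e-12, max_iter: int = 100_000
) -> dict[str, float]:
    """Fixed-point iteration ``TL <- 1 + D @ TL`` from ``TL = 1``.

    Independent cross-check of :func:`compute_trophic_levels`; converges for
    any web whose loops dilute through basal paths.
    """
    ids = web.node_ids
    index = {nid: i for i, nid in enumerate(ids)}
    prey = _prey_map(web)
    tl = np.ones(len(ids))
    for _ in range(max_iter):
        new = np.ones(len(ids))
        for nid, plist in prey.items():
            if plist:
                new[index[nid]] = 1.0 + np.mean([tl[index[p]] for p in plist])
        if np.max(np.abs(new - tl)) < tol:
            tl = new
            break
        tl = new
    else:
        raise TrophicLevelError(
            f"web {web.web_id!r}: fixed-point iteration did not converge"
        )
    return {nid: float(tl[index[nid]]) for nid in ids}


def compute_omnivory(
    web: FoodWeb, trophic_levels: Mapping[str, float]
) -> dict[str, float]:
    """Population variance (denominator = number of prey) of each consumer's
    prey trophic levels.  Nodes without prey are absent from the result;
    single-prey consumers get 0."""
    out: dict[str, float] = {}
    for nid, plist in _prey_map(web).items():
        if not plist:
            continue
        missing = [p for p in plist if p not in trophic_levels]
        if missing:
            raise TrophicLevelError(
                f"web {web.web_id!r}: prey {missing} of {nid!r} have no "
                "trophic level"
            )
        tls = np.array([trophic_levels[p] for p in plist])
        out[nid] = float(np.var(tls))  # ddof=0: prey set is the population
    return out


def compute_degree(web: FoodWeb) -> dict[str, tuple[int, int]]:
    """Per node ``(generality, vulnerability)``: prey out-degree and consumer
    in-degree, self-links excluded."""
    gen = {n.node_id: 0 for n in web.nodes}
    vul = {n.node_id: 0 for n in web.nodes}
    for l in web.links:
        if l.is_self_link:
            continue
        gen[l.consumer_id] += 1
        vul[l.resource_id] += 1
    return {nid: (gen[nid], vul[nid]) for nid in gen}


def compute_ppmr(web: FoodWeb) -> dict[str, float]:
    """log10 predator-prey body-mass ratio per consumer.

    Ratio of the predator's mean body mass to the unweighted arithmetic mean
    of its prey body masses; consumers whose prey all lack positive mass are
    omitted with a log entry.
    """
    node = web._node_map
    out: dict[str, float] = {}
    for nid, plist in _prey_map(web).items():
        if not plist:
            continue
        masses = [node[p].body_mass for p in plist if node[p].body_mass > 0]
        if not masses:
            logger.warning(
                "web %s: PPmR undefined for %s (no positive prey masses)",
                web.web_id,
                nid,
            )
            continue
        out[nid] = float(np.log10(node[nid].body_mass / np.mean(masses)))
    return out


def compute_metrics(web: FoodWeb) -> dict[str, TrophicMetrics]:
    """All per-node metrics for one web, keyed by node id."""
    tl = compute_trophic_levels(web)
    omn = compute_omnivory(web, tl)
    deg = compute_degree(web)
    ppmr = compute_ppmr(web)
    return {
        nid: TrophicMetrics(
            node_id=nid,
            trophic_level=tl[nid],
            omnivory=omn.get(nid),
            generality=deg[nid][0],
            vulnerability=deg[nid][1],
            ppmr_log10=ppmr.get(nid),
        )
        for nid in tl
    }


def metrics_table(webs: Iterable[FoodWeb]) -> pd.DataFrame:
    """Tidy per-node metrics for a collection of webs."""
    rows = []
    for w in webs:
        for m in compute_metrics(w).values():
            rows.append(
                {
                    "web_id": w.web_id,
                    "node_id": m.node_id,
                    "trophic_level": m.trophic_level,
                    "omnivory": m.omnivory,
                    "generality": m.generality,
                    "vulnerability": m.vulnerability,
                    "ppmr_log10": m.ppmr_log10,
                }
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
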