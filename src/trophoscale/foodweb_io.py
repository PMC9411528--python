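"""Food-web data model and CSV readers/writers.

A food web is a community: taxon nodes carrying mean individual body mass
(g dry weight) and numerical abundance (individuals per m^2), plus directed
feeding links from consumer to resource.  Several webs, each labelled with
an ecosystem type, make up a dataset.

The on-disk dialect is two CSV tables:

* nodes:  ``web_id, ecosystem_type, node_id, taxon_name, body_mass_g,
  abundance_per_m2, is_basal, is_aggregate`` (booleans as 0/1)
* links:  ``web_id, consumer_id, resource_id``

An optional column-mapping (``{"columns": {canonical: source_name}}``,
typically loaded from YAML) adapts exports whose headers differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("trophoscale")

ECOSYSTEM_TYPES = ("freshwater", "marine", "terrestrial")

NODE_COLUMNS = [
    "web_id",
    "ecosystem_type",
    "node_id",
    "taxon_name",
    "body_mass_g",
    "abundance_per_m2",
    "is_basal",
    "is_aggregate",
]
LINK_COLUMNS = ["web_id", "consumer_id", "resource_id"]


class FoodWebFormatError(ValueError):
    """A source table is missing mandatory columns or is otherwise unreadable."""


class FoodWebValidationError(ValueError):
    """Tables parsed but violate web-level invariants (e.g. dangling links)."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon in a web.

    ``body_mass`` is the mean individual body mass in g dry weight (> 0 for
    nodes retained in analysis); ``abundance`` is numerical density per m^2.
    ``is_aggregate`` flags coarse taxonomic groupings such as "zooplankton".
    """

    node_id: str
    taxon_name: str
    body_mass: float
    abundance: float
    is_basal: bool = False
    is_aggregate: bool = False


@dataclass(frozen=True)
class TrophicLink:
    """Directed feeding link: the consumer eats the resource."""

    consumer_id: str
    resource_id: str

    @property
    def is_self_link(self) -> bool:
        return self.consumer_id == self.resource_id


@dataclass
class FoodWeb:
    """A single community: nodes, feeding links and an ecosystem label."""

    web_id: str
    ecosystem_type: str
    nodes: list[TaxonNode] = field(default_factory=list)
    links: list[TrophicLink] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FoodWebValidationError(
                f"web {self.web_id!r}: duplicate node ids {dupes}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def node(self, node_id: str) -> TaxonNode:
        return self._node_map[node_id]

    @property
    def _node_map(self) -> dict[str, TaxonNode]:
        return {n.node_id: n for n in self.nodes}

    def prey_of(self, consumer_id: str, include_self: bool = False) -> list[str]:
        """Resource ids eaten by ``consumer_id`` (self-links dropped by default)."""
        return [
            l.resource_id
            for l in self.links
            if l.consumer_id == consumer_id
            and (include_self or not l.is_self_link)
        ]

    def consumers_of(self, resource_id: str, include_self: bool = False) -> list[str]:
        """Consumer ids feeding on ``resource_id`` (self-links dropped by default)."""
        return [
            l.consumer_id
            for l in self.links
            if l.resource_id == resource_id
            and (include_self or not l.is_self_link)
        ]

    def basal_ids(self) -> list[str]:
        """Nodes with no outgoing prey links (ignoring self-links)."""
        has_prey = {l.consumer_id for l in self.links if not l.is_self_link}
        return [n.node_id for n in self.nodes if n.node_id not in has_prey]


def _apply_mapping(
    df: pd.DataFrame, mapping: Mapping[str, str] | None, required: Sequence[str]
) -> pd.DataFrame:
    if mapping:
        rename = {src: canon for canon, src in mapping.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FoodWebFormatError(f"missing mandatory column(s): {missing}")
    return df


def read_web_tables(
    nodes_source,
    links_source,
    column_mapping: Mapping[str, Mapping[str, str]] | None = None,
) -> list[FoodWeb]:
    """Read node and link CSVs into one :class:`FoodWeb` per distinct web_id.

    Rows with non-positive body mass or missing abundance are dropped (with
    their links) and the count logged.  Self-links (cannibalism) are retained
    on the web but flagged by :attr:`TrophicLink.is_self_link`; downstream
    metric computations exclude them.  A node whose ``is_basal`` flag
    disagrees with the link structure is repaired with a warning.

    Parameters
    ----------
    nodes_source, links_source
        Paths or file-like CSV streams in the documented dialect.
    column_mapping
        Optional ``{"columns": {canonical: source_name}}`` rename map.
    """
    mapping = (column_mapping or {}).get("columns")
    nodes = _apply_mapping(
        pd.read_csv(
            nodes_source,
            dtype={"node_id": str, "web_id": str},
            float_precision="round_trip",
        ),
        mapping,
        NODE_COLUMNS,
    )
    links = _apply_mapping(
        pd.read_csv(
            links_source,
            dtype={"web_id": str, "consumer_id": str, "resource_id": str},
        ),
        mapping,
        LINK_COLUMNS,
    )

    bad = nodes["body_mass_g"].isna() | (nodes["body_mass_g"] <= 0)
    bad |= nodes["abundance_per_m2"].isna()
    dropped_ids: dict[str, set[str]] = {}
    if bad.any():
        logger.warning(
            "dropping %d node row(s) with non-positive body mass or missing "
            "abundance",
            int(bad.sum()),
        )
        for wid, grp in nodes[bad].groupby("web_id"):
            dropped_ids[str(wid)] = set(grp["node_id"].astype(str))
        nodes = nodes[~bad]

    webs: list[FoodWeb] = []
    link_groups = dict(tuple(links.groupby("web_id", sort=False)))
    for web_id, ntab in nodes.groupby("web_id", sort=False):
        eco = str(ntab["ecosystem_type"].iloc[0])
        node_objs = [
            TaxonNode(
                node_id=str(r.node_id),
                taxon_name=str(r.taxon_name),
                body_mass=float(r.body_mass_g),
                abundance=float(r.abundance_per_m2),
                is_basal=bool(int(r.is_basal)),
                is_aggregate=bool(int(r.is_aggregate)),
            )
            for r in ntab.itertuples()
        ]
        known = {n.node_id for n in node_objs}
        ltab = link_groups.get(web_id)
        link_objs: list[TrophicLink] = []
        dangling: list[tuple[str, str]] = []
        dropped_links = 0
        if ltab is not None:
            seen: set[tuple[str, str]] = set()
            removed = dropped_ids.get(str(web_id), set())
            for r in ltab.itertuples():
                pair = (str(r.consumer_id), str(r.resource_id))
                if pair in seen:
                    continue
                seen.add(pair)
                if pair[0] in known and pair[1] in known:
                    link_objs.append(TrophicLink(*pair))
                elif pair[0] in removed or pair[1] in removed:
                    dropped_links += 1  # endpoint was a dropped node row
                else:
                    dangling.append(pair)
        if dangling:
            raise FoodWebValidationError(
                f"web {web_id!r}: links reference unknown node(s): {dangling}"
            )
        if dropped_links:
            logger.warning(
                "web %s: dropped %d link(s) attached to removed nodes",
                web_id,
                dropped_links,
            )
        web = FoodWeb(str(web_id), eco, node_objs, link_objs)
        web = _reconcile_basal_flags(web)
        webs.append(web)
    return webs


def _reconcile_basal_flags(web: FoodWeb) -> FoodWeb:
    """Force ``is_basal`` to agree with the link structure, warning on mismatch."""
    basal = set(web.basal_ids())
    fixed_nodes = []
    n_fixed = 0
    for n in web.nodes:
        should = n.node_id in basal
        if n.is_basal != should:
            n_fixed += 1
            n = replace(n, is_basal=should)
        fixed_nodes.append(n)
    if n_fixed:
        logger.warning(
            "web %s: repaired %d is_basal flag(s) inconsistent with links",
            web.web_id,
            n_fixed,
        )
    return FoodWeb(web.web_id, web.ecosystem_type, fixed_nodes, web.links)


def webs_to_frames(webs: Iterable[FoodWeb]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten webs into the canonical (nodes, links) table pair."""
    node_rows = []
    link_rows = []
    for w in webs:
        for n in w.nodes:
            node_rows.append(
                {
                    "web_id": w.web_id,
                    "ecosystem_type": w.ecosystem_type,
                    "node_id": n.node_id,
                    "taxon_name": n.taxon_name,
                    "body_mass_g": n.body_mass,
                    "abundance_per_m2": n.abundance,
                    "is_basal": int(n.is_basal),
                    "is_aggregate": int(n.is_aggregate),
                }
            )
        for l in w.links:
            link_rows.append(
                {
                    "web_id": w.web_id,
                    "consumer_id": l.consumer_id,
                    "resource_id": l.resource_id,
                }
            )
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    links = pd.DataFrame(link_rows, columns=LINK_COLUMNS)
    return nodes, links


def write_web_tables(
    webs: Iterable[FoodWeb], destination: str | Path
) -> tuple[Path, Path]:
    """Write webs as ``nodes.csv`` + ``links.csv`` under ``destination``.

    Numeric fields are written with ``repr`` round-trip precision so that
    re-reading reproduces the input field-for-field.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    nodes, links = webs_to_frames(webs)
    nodes_path = dest / "nodes.csv"
    links_path = dest / "links.csv"
    nodes.to_csv(nodes_path, index=False, float_format="%.17g")
    links.to_csv(links_path, index=False)
    return nodes_path, links_path
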