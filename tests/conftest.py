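import numpy as np
import pytest

from trophoscale import (
    FoodWeb,
    SyntheticConfig,
    TaxonNode,
    TrophicLink,
    generate_dataset,
)


def make_web(web_id, eco, nodes, links):
    """nodes: (id, mass, abundance) or (id, mass, abundance, is_aggregate)."""
    node_objs = []
    consumer_ids = {c for c, r in links if c != r}
    for entry in nodes:
        nid, mass, ab = entry[:3]
        agg = bool(entry[3]) if len(entry) > 3 else False
        node_objs.append(
            TaxonNode(
                node_id=nid,
                taxon_name=f"sp_{nid}",
                body_mass=mass,
                abundance=ab,
                is_basal=nid not in consumer_ids,
                is_aggregate=agg,
            )
        )
    return FoodWeb(web_id, eco, node_objs, [TrophicLink(c, r) for c, r in links])


@pytest.fixture
def chain_web():
    """C eats B eats A (A basal)."""
    return make_web(
        "chain",
        "freshwater",
        [("A", 0.001, 1000.0), ("B", 0.1, 50.0), ("C", 10.0, 1.0)],
        [("B", "A"), ("C", "B")],
    )


@pytest.fixture
def omnivore_web():
    """O eats basal A (TL 1) and herbivore B (TL 2): TL_O = 2.5."""
    return make_web(
        "omni",
        "marine",
        [("A", 0.001, 1000.0), ("B", 0.1, 50.0), ("O", 5.0, 2.0)],
        [("B", "A"), ("O", "A"), ("O", "B")],
    )


@pytest.fixture
def cycle_web():
    """X and Y eat each other; both also eat basal A, so TLs stay defined."""
    return make_web(
        "cycle",
        "marine",
        [("A", 0.001, 1000.0), ("X", 1.0, 5.0), ("Y", 1.0, 4.0)],
        [("X", "A"), ("Y", "A"), ("X", "Y"), ("Y", "X")],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 3-ecosystem synthetic dataset (5 webs each)."""
    cfg = SyntheticConfig(n_webs_per_ecosystem=5, seed=42)
    webs, truth = generate_dataset(cfg)
    return webs, truth, cfg


def random_dag_web(rng: np.random.Generator, web_id="rnd", eco="freshwater"):
    """Small random niche-ordered acyclic web, independent of the package
    generator: node i may eat any subset of nodes with lower index."""
    s = int(rng.integers(5, 15))
    n_basal = int(rng.integers(1, 3))
    nodes = []
    links = []
    for i in range(s):
        nodes.append((f"n{i}", float(10 ** rng.normal(0, 1)), float(rng.uniform(0, 100))))
        if i >= n_basal:
            n_prey = int(rng.integers(1, i + 1))
            prey = rng.choice(i, size=n_prey, replace=False)
            links.extend((f"n{i}", f"n{int(p)}") for p in prey)
    return make_web(web_id, eco, nodes, links)
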