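"""Deterministic test data: packaged example records and simulated trees.

Two kinds of fixtures live here. First, small published-style records
packaged with the library: a four-species bird table (Lazuli bunting,
Malachite kingfisher, Amethyst sunbird, Emerald cuckoo) in the full 16-row
vectorized format with CIs and study counts, plus a thrush/fairywren pair
at 35 MYA. Second, simulated pure-birth (Yule) ultrametric trees with a
prescribed tip count and crown age, which stand in for retrieved genus
trees; the packaged genus trees are synthetic in topology and node ages
(only the crown ages 4.73 and 9.0 MY and the tip counts 12 and 11 are
fixed by design), though their tips carry real congener binomials.

Corruption helpers blank or skew chosen pairs so validation and repair
workflows can be exercised deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

import dendropy
import numpy as np

from .divergence_data import (
    DivergenceDataError,
    DivergencePair,
    PairwiseTable,
    normalize_name,
    read_table_csv,
)
from .timetrees import TimeTree

__all__ = [
    "YuleSimConfig",
    "simulate_yule_tree",
    "table1_fixture",
    "usage_pair_fixture",
    "corrupt_table",
    "COMMON_NAMES",
    "CATHARUS_SPECIES",
    "MALURUS_SPECIES",
]

#: Common-name aliases for the four packaged table species (the published
#: table prints common names; retrieval queries use binomials).
COMMON_NAMES: dict[str, str] = {
    "Lazuli bunting": "Passerina amoena",
    "Malachite kingfisher": "Corythornis cristatus",
    "Amethyst sunbird": "Chalcomitra amethystine",
    "Emerald cuckoo": "Chrysococcyx cupreus",
}

#: Real congener binomials used as tip labels on the synthetic genus trees.
CATHARUS_SPECIES = [
    "Catharus ustulatus",
    "Catharus guttatus",
    "Catharus fuscescens",
    "Catharus minimus",
    "Catharus bicknelli",
    "Catharus aurantiirostris",
    "Catharus fuscater",
    "Catharus occidentalis",
    "Catharus frantzii",
    "Catharus mexicanus",
    "Catharus dryas",
    "Catharus gracilirostris",
]
MALURUS_SPECIES = [
    "Malurus cyaneus",
    "Malurus splendens",
    "Malurus lamberti",
    "Malurus amabilis",
    "Malurus pulcherrimus",
    "Malurus elegans",
    "Malurus coronatus",
    "Malurus cyanocephalus",
    "Malurus alboscapulatus",
    "Malurus melanocephalus",
    "Malurus leucopterus",
]

#: Fixed seeds for the packaged genus trees (arbitrary constants; what
#: matters is that regeneration is bit-reproducible).
CATHARUS_TREE_SEED = 1201
MALURUS_TREE_SEED = 1101
CATHARUS_CROWN_MY = 4.73
MALURUS_CROWN_MY = 9.0


@dataclass(frozen=True)
class YuleSimConfig:
    """Configuration for a pure-birth simulation with fixed crown age."""

    n_tips: int
    crown_age_mya: float
    seed: int
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("a tree needs at least 2 tips")
        if self.crown_age_mya <= 0:
            raise ValueError("crown age must be positive")
        if self.labels is not None and len(self.labels) != self.n_tips:
            raise ValueError("labels length must equal n_tips")


def simulate_yule_tree(config: YuleSimConfig) -> TimeTree:
    """Simulate a pure-birth (Yule) tree, rescaled to an exact crown age.

    Starting from the crown split (2 lineages at time 0), an extant
    lineage chosen uniformly at random splits after an exponential waiting
    time with total rate proportional to the number of extant lineages.
    After the last split the tree grows for one more exponential draw, all
    tips are extended to the present, and every branch is rescaled so the
    root height equals ``crown_age_mya`` exactly. The output is ultrametric
    by construction and bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    root = tree.seed_node
    birth_time: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):  # crown split
        child = dendropy.Node()
        root.add_child(child)
        birth_time[child] = 0.0
        active.append(child)

    while len(active) < config.n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = t - birth_time[parent]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            active.append(child)

    present = t + rng.exponential(1.0 / config.n_tips)
    scale = config.crown_age_mya / present
    for node in active:
        node.edge.length = present - birth_time[node]
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    labels = config.labels or tuple(
        f"T{i + 1:02d}" for i in range(config.n_tips)
    )
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon = taxa.new_taxon(label=normalize_name(label))
    return TimeTree(tree)


def _packaged(name: str) -> str:
    return resources.files("divtime.data").joinpath(name).read_text("utf-8")


def table1_fixture(common_names: bool = False) -> PairwiseTable:
    """The packaged four-species 16-row full divergence table.

    Off-diagonal medians are 70.0, 27.6 and 80.0 MY with CIs 64.5–80.0,
    25.4–38.1 and 73.7–97.3 and study counts 16, 5 and 3; the diagonal is
    zero. Scientific names by default; ``common_names=True`` relabels rows
    with the published common names.
    """
    import io

    table = read_table_csv(io.StringIO(_packaged("four_species_table.csv")))
    if not common_names:
        return table
    to_common = {v: k for k, v in COMMON_NAMES.items()}
    rows = [
        replace(r, taxon_a=to_common[r.taxon_a], taxon_b=to_common[r.taxon_b])
        for r in table.rows
    ]
    return PairwiseTable(
        species=[to_common[s] for s in table.species],
        rows=rows,
        mode=table.mode,
    )


def usage_pair_fixture() -> DivergencePair:
    """The worked pair example: Swainson's thrush × Superb fairywren, 35 MYA."""
    return DivergencePair("Catharus ustulatus", "Malurus cyaneus", 35.0)


def packaged_tree(genus: str) -> TimeTree:
    """Load a packaged synthetic genus tree ("Catharus" or "Malurus")."""
    from .timetrees import parse_newick

    name = {"catharus": "catharus_synthetic.nwk", "malurus": "malurus_synthetic.nwk"}
    key = genus.strip().lower()
    if key not in name:
        raise KeyError(f"no packaged tree for {genus!r}")
    return parse_newick(_packaged(name[key]))


def corrupt_table(
    table: PairwiseTable,
    drop: Sequence[tuple[str, str]] = (),
    skew: Optional[tuple[tuple[str, str], float]] = None,
    seed: int = 0,
) -> PairwiseTable:
    """Return a copy with chosen pairs blanked and/or one ordering skewed.

    ``drop`` pairs get a missing time in both orderings; ``skew`` shifts
    the reverse ordering of one pair by ``delta`` MY, planting a
    detectable asymmetry. Unknown pairs raise. ``seed`` is accepted for
    interface symmetry; the corruption itself is deterministic.
    """
    del seed
    keys = {r.key() for r in table.rows}
    rows = list(table.rows)

    def locate(a: str, b: str) -> list[int]:
        a, b = normalize_name(a), normalize_name(b)
        if (a, b) not in keys and (b, a) not in keys:
            raise DivergenceDataError(f"pair ({a}, {b}) not in table")
        return [
            i for i, r in enumerate(rows) if r.key() in ((a, b), (b, a))
        ]

    for a, b in drop:
        for i in locate(a, b):
            rows[i] = replace(
                rows[i], time_mya=None, ci_low_mya=None, ci_high_mya=None,
                n_studies=None,
            )
    if skew is not None:
        (a, b), delta = skew
        a, b = normalize_name(a), normalize_name(b)
        hit = [i for i, r in enumerate(rows) if r.key() == (b, a)]
        if not hit:
            raise DivergenceDataError(
                f"no reverse-ordering row ({b}, {a}) to skew"
            )
        for i in hit:
            rows[i] = replace(rows[i], time_mya=rows[i].time_mya + delta)
    return PairwiseTable(species=list(table.species), rows=rows, mode=table.mode)
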