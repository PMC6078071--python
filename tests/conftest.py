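"""Shared fixtures and random-structure generators."""

from __future__ import annotations

import random

import numpy as np
import pytest

from plastorigin.taxa import TaxonMap
from plastorigin.trees import GeneTree, Node, SupportPair


def random_unrooted_topology(
    rng: random.Random, tip_names: list[str], with_lengths: bool = False
) -> GeneTree:
    """Random binary unrooted tree (trifurcating root) over the given tips."""
    assert len(tip_names) >= 3
    nodes = [Node(name=t) for t in tip_names]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(Node(children=[a, b]))
    tree = GeneTree(Node(children=nodes))
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        if with_lengths:
            node.length = round(rng.uniform(0.01, 1.0), 4)
        if not node.is_leaf:
            node.support = SupportPair()
    return tree


def random_supports(rng: random.Random, tree: GeneTree) -> None:
    """Assign random (possibly absent) support pairs to internal edges."""
    for node in tree.iter_nodes():
        if node is tree.root or node.is_leaf:
            continue
        mlbp = round(rng.uniform(0, 100), 1) if rng.random() < 0.8 else None
        bpp = round(rng.uniform(0, 1), 2) if rng.random() < 0.8 else None
        node.support = SupportPair(mlbp=mlbp, bpp=bpp)


def random_taxon_assignment(
    rng: random.Random, tips: list[str], query: str
) -> TaxonMap:
    """Random roles: one host group, one endo group, outgroup, and optionally
    donors / heterotrophs; the query tip stays unmapped."""
    others = [t for t in tips if t != query]
    rng.shuffle(others)
    groups = ["host", "endo", "out"]
    if rng.random() < 0.6:
        groups.append("donor1")
    if rng.random() < 0.3:
        groups.append("donor2")
    if rng.random() < 0.4:
        groups.append("het")
    tip_to_group: dict[str, str] = {}
    # guarantee one tip per mandatory group, then spread the rest
    for group, tip in zip(groups, others):
        tip_to_group[tip] = group
    for tip in others[len(groups) :]:
        tip_to_group[tip] = rng.choice(groups)
    roles = {
        "host": "host_vertical",
        "endo": "endosymbiont",
        "out": "outgroup",
        "donor1": "donor",
        "donor2": "donor",
        "het": "heterotroph",
    }
    group_to_role = {g: roles[g] for g in groups}
    return TaxonMap(tip_to_group, group_to_role, query_tips={query})


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240803)


@pytest.fixture
def np_rng() -> np.random.Generator:
    return np.random.default_rng(20240803)
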