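"""Synthetic gene families with a known origin scenario.

Builds a group-structured scenario tree (host, endosymbiont, donor,
heterotroph and outgroup clades) with a query tip grafted according to a
VI / EA / LA scenario, and evolves amino-acid alignments on it under the
Poisson (equal-rates, 20-state) model.  Along a branch of length ``d``
(expected substitutions per site) a site differs from its parent with
probability ``(19/20) * (1 - exp(-20 d / 19))``; this closed form is the
exact inverse of :func:`plastorigin.reconstruct.poisson_correct`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .alignment import AMINO_ACIDS, MSA
from .taxa import TaxonMap
from .trees import GeneTree, Node

SCENARIOS = ("VI", "EA", "LA")
GRAFT_DEPTHS = ("nested", "sister")
N_STATES = 20

__all__ = [
    "SCENARIOS",
    "ScenarioParams",
    "ScenarioTruth",
    "build_scenario_tree",
    "simulate_alignment",
    "expected_mismatch",
    "scenario_taxon_map",
]


@dataclass(frozen=True)
class ScenarioParams:
    scenario: str
    n_host: int = 6
    n_endo: int = 6
    n_outgroup: int = 3
    n_heterotroph: int = 2
    donor_groups: tuple[tuple[str, int], ...] = (("donorA", 4), ("donorB", 4))
    internal_branch: float = 0.3
    terminal_branch: float = 0.1
    graft_depth: str = "nested"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.graft_depth not in GRAFT_DEPTHS:
            raise ValueError(f"graft_depth must be one of {GRAFT_DEPTHS}")
        for label, n in (
            ("n_host", self.n_host),
            ("n_endo", self.n_endo),
            ("n_outgroup", self.n_outgroup),
            ("n_heterotroph", self.n_heterotroph),
        ):
            if n < 2:
                raise ValueError(f"{label} must be >= 2 (clades must be testable)")
        if not self.donor_groups:
            raise ValueError("need at least one donor group")
        for name, n in self.donor_groups:
            if n < 2:
                raise ValueError(f"donor group {name!r} must have >= 2 tips")
        if self.internal_branch <= 0 or self.terminal_branch <= 0:
            raise ValueError("branch lengths must be > 0")


@dataclass(frozen=True)
class ScenarioTruth:
    scenario: str
    donor_group: str
    query_id: str
    true_tree: GeneTree

    def to_json(self) -> str:
        from .trees import write_newick

        return json.dumps(
            {
                "scenario": self.scenario,
                "donor_group": self.donor_group,
                "query_id": self.query_id,
                "true_tree": write_newick(self.true_tree),
            },
            indent=2,
        )


QUERY_ID = "query1"


def _group_clade(
    names: list[str], terminal: float, internal: float
) -> Node:
    """Balanced clade over the given tip names (keeps tip depths shallow so
    corrected distances stay well below the saturation ceiling)."""
    if len(names) == 1:
        return Node(name=names[0], length=terminal)
    mid = len(names) // 2
    left = _group_clade(names[:mid], terminal, internal)
    right = _group_clade(names[mid:], terminal, internal)
    return Node(length=internal, children=[left, right])


def scenario_group_names(p: ScenarioParams) -> dict[str, list[str]]:
    groups = {
        "host": [f"host{i}" for i in range(1, p.n_host + 1)],
        "endo": [f"endo{i}" for i in range(1, p.n_endo + 1)],
        "het": [f"het{i}" for i in range(1, p.n_heterotroph + 1)],
        "out": [f"out{i}" for i in range(1, p.n_outgroup + 1)],
    }
    for name, n in p.donor_groups:
        groups[name] = [f"{name}{i}" for i in range(1, n + 1)]
    return groups


def scenario_taxon_map(p: ScenarioParams) -> TaxonMap:
    groups = scenario_group_names(p)
    roles = {
        "host": "host_vertical",
        "endo": "endosymbiont",
        "het": "heterotroph",
        "out": "outgroup",
    }
    for name, _ in p.donor_groups:
        roles[name] = "donor"
    tip_to_group = {
        tip: group for group, tips in groups.items() for tip in tips
    }
    return TaxonMap(tip_to_group, roles, query_tips={QUERY_ID})


def build_scenario_tree(p: ScenarioParams) -> tuple[GeneTree, ScenarioTruth]:
    """Scenario tree with the query grafted per the generating scenario.

    Topology: ``(outgroup, (heterotroph, (donorN, ... (donor1, (endo,
    host)))))`` with the outgroup basal; the query attaches inside
    (``nested``) or as sister to (``sister``) the scenario's target clade
    (VI -> host, EA -> endosymbiont, LA -> first donor group).  Deterministic
    in ``seed`` (the seed picks the nested graft position).
    """
    rng = np.random.default_rng(p.seed)
    groups = scenario_group_names(p)
    ib, tb = p.internal_branch, p.terminal_branch

    clades = {
        name: _group_clade(tips, tb, ib) for name, tips in groups.items()
    }

    target_key = {
        "VI": "host",
        "EA": "endo",
        "LA": p.donor_groups[0][0],
    }[p.scenario]
    donor_group = {"VI": "host", "EA": "endo", "LA": p.donor_groups[0][0]}[
        p.scenario
    ]

    query = Node(name=QUERY_ID, length=tb)
    target = clades[target_key]
    if p.graft_depth == "sister":
        clades[target_key] = Node(length=ib, children=[target, query])
    else:
        # attach the query as sister to a randomly chosen tip of the target
        tip_name = str(rng.choice(groups[target_key]))
        _graft_at_tip(target, tip_name, query)

    core = Node(length=ib, children=[clades["endo"], clades["host"]])
    for name, _ in p.donor_groups:
        core = Node(length=ib, children=[clades[name], core])
    core = Node(length=ib, children=[clades["het"], core])
    root = Node(children=[clades["out"], core])
    clades["out"].length = ib

    tree = GeneTree(root)
    truth = ScenarioTruth(
        scenario=p.scenario,
        donor_group=donor_group,
        query_id=QUERY_ID,
        true_tree=tree.copy(),
    )
    return tree, truth


def _graft_at_tip(clade: Node, tip_name: str, query: Node) -> None:
    """Replace tip ``tip_name`` with a cherry ``(tip, query)`` in place."""
    for node in clade.iter_nodes():
        for i, child in enumerate(node.children):
            if child.is_leaf and child.name == tip_name:
                half = (child.length or 0.0) / 2.0
                child.length = half
                node.children[i] = Node(
                    length=half, children=[child, query]
                )
                return
    if clade.is_leaf and clade.name == tip_name:  # single-tip clade
        raise ValueError("cannot graft inside a single-tip clade")
    raise KeyError(f"tip {tip_name!r} not found for grafting")


def with_full_supports(tree: GeneTree) -> GeneTree:
    """Copy of the tree with (MLBP 100, BPP 1.0) on every internal edge, for
    feeding truth topologies straight into the classifier."""
    from .trees import SupportPair

    out = tree.copy()
    for node in out.iter_nodes():
        if node is not out.root and not node.is_leaf:
            node.support = SupportPair(mlbp=100.0, bpp=1.0)
    return out


def expected_mismatch(d: float) -> float:
    """Expected per-site mismatch fraction between the ends of a branch of
    length ``d`` under the Poisson model."""
    k = N_STATES
    return (k - 1) / k * (1.0 - math.exp(-k * d / (k - 1)))


def simulate_alignment(tree: GeneTree, length: int, seed: int) -> MSA:
    """Evolve an alignment on the tree: root sequence i.i.d. uniform over the
    20 amino acids; sites independent; no indels; deterministic in seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, N_STATES, size=length)
    rows: dict[str, str] = {}

    def evolve(parent_seq: np.ndarray, node: Node) -> None:
        if node.length is None:
            raise ValueError("tree has a branch without length; cannot simulate")
        p_change = expected_mismatch(node.length)
        changed = rng.random(length) < p_change
        seq = parent_seq.copy()
        n_changed = int(changed.sum())
        if n_changed:
            # uniform over the 19 non-parent states
            offsets = rng.integers(1, N_STATES, size=n_changed)
            seq[changed] = (seq[changed] + offsets) % N_STATES
        if node.is_leaf:
            rows[node.name] = "".join(AMINO_ACIDS[i] for i in seq)
        else:
            for child in node.children:
                evolve(seq, child)

    for child in tree.root.children:
        evolve(root_seq, child)
    if tree.root.is_leaf:
        rows[tree.root.name] = "".join(AMINO_ACIDS[i] for i in root_seq)
    return MSA(rows)


def write_truth(truth: ScenarioTruth, path: Union[str, Path]) -> None:
    Path(path).write_text(truth.to_json() + "\n")
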