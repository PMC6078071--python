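"""Independent brute-force oracles used to cross-check the package.

Everything here applies the decision rules literally over exhaustively
enumerated clades, with its own traversal code, and must stay independent of
the code paths it checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from plastorigin.classify import ClassificationConfig, evaluate_support
from plastorigin.taxa import TaxonMap
from plastorigin.trees import GeneTree, Node, SupportPair


# ---------------------------------------------------------------------------
# edge / clade enumeration (own recursion, not GeneTree.clades())
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    below: frozenset[str]
    support: SupportPair


def enumerate_edges(tree: GeneTree) -> tuple[frozenset[str], list[Edge]]:
    """All edges of the (unrooted-interpreted) tree as (tip-side, support)."""
    edges: list[Edge] = []

    def visit(node: Node) -> frozenset[str]:
        if not node.children:
            below = frozenset([node.name])
        else:
            below = frozenset().union(*(visit(c) for c in node.children))
        if node is not tree.root:
            sup = node.support if node.support is not None else SupportPair()
            edges.append(Edge(below, sup))
        return below

    all_tips = visit(tree.root)
    return all_tips, edges


def rooted_clades(
    tree: GeneTree, tmap: TaxonMap
) -> list[tuple[frozenset[str], SupportPair]]:
    """Every clade (with its edge support) of the tree rooted on the edge
    that best isolates the outgroup: maximal outgroup tips on one side, then
    minimal non-outgroup tips, then lexicographically smallest tip set."""
    all_tips, edges = enumerate_edges(tree)
    out_tips = {t for t in all_tips if tmap.role_of(t) == "outgroup"}
    assert out_tips, "oracle requires outgroup tips"

    best_key = None
    root_edge = None
    root_side = None
    for edge in edges:
        for side in (edge.below, all_tips - edge.below):
            key = (
                -len(side & out_tips),
                len(side - out_tips),
                tuple(sorted(side)),
            )
            if best_key is None or key < best_key:
                best_key, root_edge, root_side = key, edge, side

    R = root_side
    C = all_tips - R
    clades = [(R, root_edge.support), (C, root_edge.support)]
    for edge in edges:
        if edge.below in (R, C) or (all_tips - edge.below) in (R, C):
            continue  # the root edge itself
        for side in (edge.below, all_tips - edge.below):
            if side < R or side < C:  # proper subset of a root child
                clades.append((side, edge.support))
                break
    return clades


# ---------------------------------------------------------------------------
# literal rule cascade
# ---------------------------------------------------------------------------


def brute_force_classify(
    tree: GeneTree, query: str, tmap: TaxonMap, cfg: ClassificationConfig
) -> str:
    """Literal application of the decision cascade; returns the call string."""
    tips = set(tree.tips())
    informative_tree = [
        t for t in tips if t != query and t not in tmap.coquery_tips
    ]
    if len(tips) < 4 or not informative_tree:
        return "UNCERTAIN"

    clades = rooted_clades(tree, tmap)
    host_group = tmap.single_group("host_vertical")
    endo_group = tmap.single_group("endosymbiont")

    # (1) smallest supported enclosing clade with at least one informative
    # tip (clades of only query + co-query tips are transparent)
    enclosing = [
        (c, s)
        for c, s in clades
        if query in c
        and len(c) >= 2
        and evaluate_support(s, cfg)
        and any(t != query and t not in tmap.coquery_tips for t in c)
    ]
    chosen = min(enclosing, key=lambda cs: len(cs[0])) if enclosing else None

    if chosen is not None:
        clade, _sup = chosen
        informative = [
            t for t in clade if t != query and t not in tmap.coquery_tips
        ]
        if informative:
            n = len(informative)

            def pure(group: str) -> bool:
                inside = sum(
                    1 for t in informative if tmap.group_of(t) == group
                )
                return inside > 0 and n - inside <= cfg.max_foreign_tips

            if pure(host_group):
                return "VI"
            if pure(endo_group):
                return "EA"
            for group in sorted(
                {
                    tmap.group_of(t)
                    for t in informative
                    if tmap.role_of(t) == "donor"
                }
            ):
                if pure(group):
                    return "LA"
            het = [t for t in informative if tmap.role_of(t) == "heterotroph"]
            if het and n - len(het) <= cfg.max_foreign_tips:
                return "UNCERTAIN"

    # (4) exclusion-based LA
    if cfg.allow_exclusion_la:

        def reference_supported(group: str) -> bool:
            group_tips = {
                t
                for t in tips
                if tmap.group_of(t) == group
                and t != query
                and t not in tmap.coquery_tips
            }
            if not group_tips:
                return False
            for clade, sup in clades:
                if len(clade) < 2 or query in clade:
                    continue
                informative = {t for t in clade if t not in tmap.coquery_tips}
                inside = len(informative & group_tips)
                foreign = len(informative - group_tips)
                missing = len(group_tips) - inside
                if (
                    missing <= cfg.max_foreign_tips
                    and foreign <= cfg.max_foreign_tips
                    and evaluate_support(sup, cfg)
                ):
                    return True
            return False

        if reference_supported(host_group) and reference_supported(endo_group):
            return "LA"

    return "UNCERTAIN"
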