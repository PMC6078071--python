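"""Origin typing of a query protein from a supported gene tree.

The decision procedure walks rootward from the query tip to the smallest
clade whose subtending edge is statistically supported, tests the taxonomic
composition of that clade, and emits one of four calls:

* ``VI`` -- nested among the vertically inheriting host group,
* ``EA`` -- nested among the endosymbiont group,
* ``LA`` -- nested in a single foreign donor group, or called by exclusion
  when both the host and the endosymbiont form supported clades that do not
  contain the query,
* ``UNCERTAIN`` -- anything else (insufficient signal).

Tips flagged as co-queries (other focal paralogs / the sister focal genus)
are transparent to every composition test.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Optional

from .extensions import ExtensionReport
from .taxa import TaxonMap
from .trees import GeneTree, Node, SupportPair

SUPPORT_RULES = ("or", "and", "mlbp_only", "bpp_only")
CALLS = ("VI", "EA", "LA", "UNCERTAIN")

__all__ = [
    "ClassificationConfig",
    "OriginCall",
    "evaluate_support",
    "root_on_outgroup",
    "prune_long_branches",
    "smallest_supported_enclosing_clade",
    "classify_query",
    "classify_all_queries",
    "flag_cytosolic",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and switches of the decision cascade.

    The source analysis never states numeric support cut-offs; the defaults
    (MLBP >= 50 OR BPP >= 0.95) reproduce its published accept/reject pattern
    and are fully configurable.
    """

    mlbp_min: float = 50.0
    bpp_min: float = 0.95
    support_rule: str = "or"
    max_foreign_tips: int = 0
    allow_exclusion_la: bool = True
    outgroup_required: bool = True
    long_branch_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mlbp_min <= 100.0:
            raise ValueError("mlbp_min must be in [0, 100]")
        if not 0.0 <= self.bpp_min <= 1.0:
            raise ValueError("bpp_min must be in [0, 1]")
        if self.support_rule not in SUPPORT_RULES:
            raise ValueError(f"support_rule must be one of {SUPPORT_RULES}")
        if self.max_foreign_tips < 0:
            raise ValueError("max_foreign_tips must be >= 0")
        if self.long_branch_factor is not None and self.long_branch_factor < 1:
            raise ValueError("long_branch_factor must be >= 1 (or None)")


@dataclass(frozen=True)
class OriginCall:
    query_id: str
    call: str
    donor_group: str = "unknown"
    evidence_clade: frozenset[str] = field(default_factory=frozenset)
    evidence_support: SupportPair = SupportPair()
    exclusion_based: bool = False
    cytosolic: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"call must be one of {CALLS}")
        if self.exclusion_based and self.call != "LA":
            raise ValueError("exclusion_based calls must be LA")
        if not self.exclusion_based and self.evidence_clade:
            if self.query_id not in self.evidence_clade:
                raise ValueError("evidence clade must contain the query")


def evaluate_support(s: SupportPair, cfg: ClassificationConfig) -> bool:
    """True iff the support pair passes the configured rule.

    An absent component always fails its own sub-test.
    """
    mlbp_ok = s.mlbp is not None and s.mlbp >= cfg.mlbp_min
    bpp_ok = s.bpp is not None and s.bpp >= cfg.bpp_min
    if cfg.support_rule == "or":
        return mlbp_ok or bpp_ok
    if cfg.support_rule == "and":
        return mlbp_ok and bpp_ok
    if cfg.support_rule == "mlbp_only":
        return mlbp_ok
    return bpp_ok


# ---------------------------------------------------------------------------
# tree preparation
# ---------------------------------------------------------------------------


def root_on_outgroup(tree: GeneTree, tmap: TaxonMap) -> GeneTree:
    """Root the tree so the outgroup-role tips sit basally.

    Picks the edge whose tip-side best isolates the outgroup (maximal
    outgroup tips, then minimal non-outgroup tips, ties broken by the
    lexicographically smallest tip set) and returns a copy rooted there.
    Raises if no outgroup tip is present.
    """
    all_tips = frozenset(tree.tips())
    out_tips = {t for t in all_tips if tmap.role_of(t) == "outgroup"}
    if not out_tips:
        raise ValueError("no outgroup tips present; cannot root on outgroup")
    clades = tree.clades()
    best: Optional[tuple] = None
    best_node: Optional[Node] = None
    for node, below in clades.items():
        if node is tree.root:
            continue
        # both orientations of the edge above this node are candidate
        # outgroup sides; rooting the edge is the same either way
        for side in (below, all_tips - below):
            n_out = len(side & out_tips)
            n_other = len(side) - n_out
            key = (-n_out, n_other, tuple(sorted(side)))
            if best is None or key < best:
                best, best_node = key, node
    assert best_node is not None
    return tree.rerooted_above(best_node)


def prune_long_branches(
    tree: GeneTree, factor: float, tmap: Optional[TaxonMap] = None
) -> tuple[GeneTree, list[str]]:
    """Drop non-query tips whose terminal branch exceeds ``factor`` x median
    terminal branch length.  Returns (pruned copy, removed tip names).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    tips = [n for n in tree.iter_nodes() if n.is_leaf]
    lengths = [n.length for n in tips]
    if any(x is None for x in lengths):
        raise ValueError(
            "tree has no (complete) branch lengths; skip long-branch pruning"
        )
    med = statistics.median(lengths)
    protected: set[str] = set()
    if tmap is not None:
        protected = tmap.query_tips | tmap.coquery_tips
    to_remove = [
        n.name
        for n in tips
        if n.name not in protected and n.length > factor * med
    ]
    if not to_remove:
        return tree.copy(), []
    pruned = tree.copy()
    for name in to_remove:
        _remove_tip(pruned, name)
    return pruned, to_remove


def _remove_tip(tree: GeneTree, name: str) -> None:
    parents = tree.parents()
    tip = tree.find_tip(name)
    parent = parents[tip]
    parent.children.remove(tip)
    # suppress the resulting unifurcation
    while len(parent.children) == 1 and parent is not tree.root:
        child = parent.children[0]
        grand = parents[parent]
        if child.length is not None and parent.length is not None:
            child.length += parent.length
        elif parent.length is not None:
            child.length = parent.length
        if child.support is None or child.support.is_absent:
            child.support = parent.support
        grand.children[grand.children.index(parent)] = child
        parent = grand
    if parent is tree.root and len(parent.children) == 1:
        only = parent.children[0]
        tree.root = only
        only.length = None
        only.support = None


# ---------------------------------------------------------------------------
# clade search and composition
# ---------------------------------------------------------------------------


def smallest_supported_enclosing_clade(
    tree: GeneTree, query: str, tmap: TaxonMap, cfg: ClassificationConfig
) -> Optional[tuple[frozenset[str], SupportPair]]:
    """First supported clade met walking rootward from the query.

    Expects a tree already rooted on the outgroup (see
    :func:`root_on_outgroup`); clades are read below the root only.
    Returns ``None`` when no enclosing edge passes the support rule.
    """
    tip = tree.find_tip(query)
    parents = tree.parents()
    node = parents.get(tip)
    clades = tree.clades()
    while node is not None and node is not tree.root:
        sup = node.support if node.support is not None else SupportPair()
        if evaluate_support(sup, cfg):
            return clades[node], sup
        node = parents.get(node)
    return None


def _supported_enclosing_clades(
    tree: GeneTree, query: str, tmap: TaxonMap, cfg: ClassificationConfig
):
    """All supported clades enclosing the query, smallest first."""
    tip = tree.find_tip(query)
    parents = tree.parents()
    node = parents.get(tip)
    clades = tree.clades()
    while node is not None and node is not tree.root:
        sup = node.support if node.support is not None else SupportPair()
        if evaluate_support(sup, cfg):
            yield clades[node], sup
        node = parents.get(node)


def _composition_call(
    clade: frozenset[str], query: str, tmap: TaxonMap, cfg: ClassificationConfig
) -> Optional[tuple[str, str, bool]]:
    """Purity test of step (3): returns (call, donor_group, cytosolic_candidate)
    or None when the clade is mixed / empty of informative tips."""
    informative = [
        t for t in clade if t != query and t not in tmap.coquery_tips
    ]
    if not informative:
        return None
    host_group = tmap.single_group("host_vertical")
    endo_group = tmap.single_group("endosymbiont")
    n = len(informative)

    def pure(group: str) -> bool:
        inside = sum(1 for t in informative if tmap.group_of(t) == group)
        return inside > 0 and n - inside <= cfg.max_foreign_tips

    # precedence: host, endosymbiont, single donor group, heterotroph
    if pure(host_group):
        return "VI", host_group, False
    if pure(endo_group):
        return "EA", endo_group, False
    donor_groups = sorted(
        {
            tmap.group_of(t)
            for t in informative
            if tmap.role_of(t) == "donor"
        }
    )
    for group in donor_groups:
        if pure(group):
            return "LA", group, False
    het = [t for t in informative if tmap.role_of(t) == "heterotroph"]
    if het and n - len(het) <= cfg.max_foreign_tips:
        return "UNCERTAIN", "unknown", True
    return None


def _reference_clade_supported(
    tree: GeneTree,
    query: str,
    tmap: TaxonMap,
    cfg: ClassificationConfig,
    group: str,
) -> Optional[tuple[frozenset[str], SupportPair]]:
    """Is there a supported clade holding (essentially all of) ``group``'s tips
    and excluding the query?  Used by the exclusion-based LA rule.

    A qualifying clade misses at most ``max_foreign_tips`` of the group's tips
    and contains at most ``max_foreign_tips`` informative tips from outside it.
    """
    group_tips = {
        t
        for t in tree.tips()
        if tmap.group_of(t) == group
        and t != query
        and t not in tmap.coquery_tips
    }
    if not group_tips:
        return None
    clades = tree.clades()
    for node, below in clades.items():
        if node is tree.root or node.is_leaf:
            continue
        if query in below:
            continue
        informative = {t for t in below if t not in tmap.coquery_tips}
        inside = len(informative & group_tips)
        foreign = len(informative - group_tips)
        missing = len(group_tips) - inside
        if missing <= cfg.max_foreign_tips and foreign <= cfg.max_foreign_tips:
            sup = node.support if node.support is not None else SupportPair()
            if evaluate_support(sup, cfg):
                return below, sup
    return None


# ---------------------------------------------------------------------------
# the decision cascade
# ---------------------------------------------------------------------------


def classify_query(
    tree: GeneTree,
    query: str,
    tmap: TaxonMap,
    cfg: Optional[ClassificationConfig] = None,
) -> OriginCall:
    """Apply the full decision cascade to one query tip."""
    cfg = cfg or ClassificationConfig()
    tips = tree.tips()
    if query not in tips:
        raise KeyError(f"query {query!r} not in tree")

    informative = [
        t for t in tips if t != query and t not in tmap.coquery_tips
    ]
    if len(tips) < 4 or not informative:
        return OriginCall(
            query_id=query,
            call="UNCERTAIN",
            notes="degenerate input: fewer than 4 tips or no non-query tips",
        )

    has_outgroup = any(tmap.role_of(t) == "outgroup" for t in tips)
    if has_outgroup:
        work = root_on_outgroup(tree, tmap)
    elif cfg.outgroup_required:
        raise ValueError("no outgroup tips in tree and outgroup_required is set")
    else:
        work = tree.copy()

    pruned_note = ""
    if cfg.long_branch_factor is not None:
        work, removed = prune_long_branches(work, cfg.long_branch_factor, tmap)
        if removed:
            pruned_note = f"long-branch tips removed: {','.join(sorted(removed))}; "
        if query not in work.tips():  # pragma: no cover - queries are protected
            raise AssertionError("query removed by pruning")

    # Walk outward over supported enclosing clades; clades containing only
    # the query and co-query tips are transparent (the focal lineage itself)
    # and the walk continues rootward past them.
    verdict = None
    clade: frozenset[str] = frozenset()
    sup = SupportPair()
    for clade, sup in _supported_enclosing_clades(work, query, tmap, cfg):
        if any(t != query and t not in tmap.coquery_tips for t in clade):
            verdict = _composition_call(clade, query, tmap, cfg)
            break
    if verdict is not None:
        call, donor_group, cytosolic_candidate = verdict
        note = pruned_note + (
            "pure heterotroph clade: cytosolic candidate"
            if cytosolic_candidate
            else ""
        )
        return OriginCall(
            query_id=query,
            call=call,
            donor_group=donor_group if call != "UNCERTAIN" else "unknown",
            evidence_clade=clade,
            evidence_support=sup,
            notes=note.strip("; "),
        )

    # step (4): exclusion-based LA
    if cfg.allow_exclusion_la:
        host_group = tmap.single_group("host_vertical")
        endo_group = tmap.single_group("endosymbiont")
        host_ref = _reference_clade_supported(work, query, tmap, cfg, host_group)
        endo_ref = _reference_clade_supported(work, query, tmap, cfg, endo_group)
        if host_ref is not None and endo_ref is not None:
            notes = pruned_note + (
                "exclusion-based: host clade "
                f"({_fmt_support(host_ref[1])}) and endosymbiont clade "
                f"({_fmt_support(endo_ref[1])}) both supported without the query"
            )
            return OriginCall(
                query_id=query,
                call="LA",
                donor_group="unknown",
                exclusion_based=True,
                notes=notes,
            )

    return OriginCall(
        query_id=query,
        call="UNCERTAIN",
        notes=(pruned_note + "no supported pure clade; exclusion test failed").strip(
            "; "
        ),
    )


def classify_all_queries(
    tree: GeneTree,
    queries: list[str],
    tmap: TaxonMap,
    cfg: Optional[ClassificationConfig] = None,
) -> list[OriginCall]:
    """Classify several query paralogs of one tree independently, each with
    the others treated as co-queries."""
    calls = []
    for query in queries:
        others = (set(queries) - {query}) | tmap.coquery_tips
        calls.append(
            classify_query(tree, query, tmap.with_queries({query}, others), cfg)
        )
    return calls


def flag_cytosolic(
    call: OriginCall,
    tmap: TaxonMap,
    ext: Optional[ExtensionReport] = None,
) -> OriginCall:
    """Mark a call as a cytosolic paralog.

    Cytosolic iff the evidence clade holds at least one heterotroph-role tip
    and no N-terminal extension is known for the query.  Cytosolic calls are
    excluded from plastid-pathway aggregation downstream.
    """
    has_het = any(
        tmap.role_of(t) == "heterotroph"
        for t in call.evidence_clade
        if t != call.query_id
    )
    if not has_het:
        return call
    if ext is not None and ext.has_extension:
        note = (call.notes + "; " if call.notes else "") + (
            "heterotroph affinity but N-terminal extension present; kept plastidial"
        )
        return replace(call, cytosolic=False, notes=note)
    return replace(call, cytosolic=True)


def _fmt_support(s: SupportPair) -> str:
    mlbp = "-" if s.mlbp is None else format(s.mlbp, "g")
    bpp = "-" if s.bpp is None else format(s.bpp, "g")
    return f"MLBP {mlbp}, BPP {bpp}"
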