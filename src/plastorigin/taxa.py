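"""Tip -> group and group -> role assignments used by the classifier."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .trees import GeneTree

ROLES = ("host_vertical", "endosymbiont", "donor", "heterotroph", "outgroup")
#: pseudo-roles accepted in a 3-column taxon file for the focal tips
QUERY_ROLES = ("query", "coquery")

__all__ = ["ROLES", "TaxonMap", "load_taxon_map", "ValidationReport", "validate"]


@dataclass
class TaxonMap:
    tip_to_group: dict[str, str]
    group_to_role: dict[str, str]
    query_tips: set[str] = field(default_factory=set)
    coquery_tips: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = sorted(set(self.group_to_role.values()) - set(ROLES))
        if bad:
            raise ValueError(f"unknown roles {bad}; legal roles are {list(ROLES)}")
        overlap = self.query_tips & self.coquery_tips
        if overlap:
            raise ValueError(f"tips both query and coquery: {sorted(overlap)}")
        missing = sorted(
            {g for g in self.tip_to_group.values() if g not in self.group_to_role}
        )
        if missing:
            raise ValueError(f"groups without a role: {missing}")

    def group_of(self, tip: str) -> str:
        """Group of a tip; unmapped tips get a private one-tip donor group."""
        return self.tip_to_group.get(tip, f"unassigned:{tip}")

    def role_of(self, tip: str) -> str:
        group = self.tip_to_group.get(tip)
        if group is None:
            return "donor"
        return self.group_to_role[group]

    def groups_with_role(self, role: str) -> list[str]:
        return sorted(g for g, r in self.group_to_role.items() if r == role)

    def single_group(self, role: str) -> str:
        groups = self.groups_with_role(role)
        if len(groups) != 1:
            raise ValueError(
                f"classification needs exactly one {role} group, found {groups}"
            )
        return groups[0]

    def with_queries(
        self, query_tips: Iterable[str], coquery_tips: Iterable[str] = ()
    ) -> "TaxonMap":
        return TaxonMap(
            dict(self.tip_to_group),
            dict(self.group_to_role),
            set(query_tips),
            set(coquery_tips),
        )


def _read_rows(path: Union[str, Path]) -> list[list[str]]:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([f.strip() for f in line.split("\t")])
    return rows


def load_taxon_map(
    path: Union[str, Path], roles_path: Optional[Union[str, Path]] = None
) -> TaxonMap:
    """Load a taxon map from TSV.

    Either a single 3-column file ``tip<TAB>group<TAB>role`` or a 2-column
    ``tip<TAB>group`` file plus a second ``group<TAB>role`` file.  Rows whose
    role is ``query``/``coquery`` mark focal tips (their group column is
    recorded but carries no reference role).
    """
    rows = _read_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty taxon map")
    tip_to_group: dict[str, str] = {}
    group_to_role: dict[str, str] = {}
    query_tips: set[str] = set()
    coquery_tips: set[str] = set()

    def note_role(group: str, role: str, where: str) -> None:
        if role not in ROLES:
            raise ValueError(
                f"{where}: unknown role {role!r}; legal roles are "
                f"{list(ROLES)} (or {list(QUERY_ROLES)} for focal tips)"
            )
        if group_to_role.get(group, role) != role:
            raise ValueError(
                f"{where}: group {group!r} assigned two roles "
                f"({group_to_role[group]!r} and {role!r})"
            )
        group_to_role[group] = role

    def note_tip(tip: str, group: str, where: str) -> None:
        if tip_to_group.get(tip, group) != group:
            raise ValueError(
                f"{where}: tip {tip!r} assigned to two groups "
                f"({tip_to_group[tip]!r} and {group!r})"
            )
        tip_to_group[tip] = group

    if roles_path is None:
        if any(len(r) != 3 for r in rows):
            raise ValueError(
                f"{path}: expected 3 columns (tip, group, role) when no "
                "separate role file is given"
            )
        for tip, group, role in rows:
            if role in QUERY_ROLES:
                (query_tips if role == "query" else coquery_tips).add(tip)
                continue
            note_role(group, role, str(path))
            note_tip(tip, group, str(path))
    else:
        if any(len(r) != 2 for r in rows):
            raise ValueError(f"{path}: expected 2 columns (tip, group)")
        for tip, group in rows:
            note_tip(tip, group, str(path))
        role_rows = _read_rows(roles_path)
        if any(len(r) != 2 for r in role_rows):
            raise ValueError(f"{roles_path}: expected 2 columns (group, role)")
        for group, role in role_rows:
            note_role(group, role, str(roles_path))
        missing = sorted(set(tip_to_group.values()) - set(group_to_role))
        if missing:
            raise ValueError(f"{roles_path}: groups without a role: {missing}")

    return TaxonMap(tip_to_group, group_to_role, query_tips, coquery_tips)


def write_taxon_map(tmap: TaxonMap, path: Union[str, Path]) -> None:
    """Write the single-file 3-column form read by :func:`load_taxon_map`."""
    lines = ["#tip\tgroup\trole"]
    for tip in sorted(tmap.tip_to_group):
        group = tmap.tip_to_group[tip]
        lines.append(f"{tip}\t{group}\t{tmap.group_to_role[group]}")
    for tip in sorted(tmap.query_tips):
        lines.append(f"{tip}\tquery\tquery")
    for tip in sorted(tmap.coquery_tips):
        lines.append(f"{tip}\tquery\tcoquery")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ValidationReport:
    unassigned_tips: list[str]
    unused_map_entries: list[str]
    outgroup_present: bool

    @property
    def is_clean(self) -> bool:
        return (
            not self.unassigned_tips
            and not self.unused_map_entries
            and self.outgroup_present
        )

    def messages(self) -> list[str]:
        out = []
        for tip in self.unassigned_tips:
            out.append(f"tip {tip!r} not in taxon map; defaulting to donor role")
        for tip in self.unused_map_entries:
            out.append(f"map entry {tip!r} absent from tree")
        if not self.outgroup_present:
            out.append("no outgroup present")
        return out


def validate(tree: GeneTree, tmap: TaxonMap) -> ValidationReport:
    """Cross-check a tree against a taxon map (report, never an exception)."""
    tree_tips = set(tree.tips())
    mapped = set(tmap.tip_to_group) | tmap.query_tips | tmap.coquery_tips
    unassigned = sorted(tree_tips - mapped)
    unused = sorted(mapped - tree_tips)
    outgroup_present = any(
        tmap.role_of(t) == "outgroup" for t in tree_tips & set(tmap.tip_to_group)
    )
    return ValidationReport(unassigned, unused, outgroup_present)
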