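"""Static registry of the three plastid-localized biosynthetic pathways.

The registry is shipped as a versioned JSON data file so it can be audited
without reading code.  It is loaded once and exposed as immutable objects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

PATHWAY_NAMES = ("heme_C5", "chlorophyll_a", "non_mevalonate")
COMPARTMENTS = ("nucleus_encoded", "plastid_encoded", "mixed", "unknown")
_KOID_RE = re.compile(r"^K\d{5}$")

__all__ = [
    "PATHWAY_NAMES",
    "EnzymeVariant",
    "PathwayStep",
    "Pathway",
    "get_pathway",
    "count_steps",
    "dual_enzyme_steps",
    "find_step",
    "dump_registry",
]


@dataclass(frozen=True)
class EnzymeVariant:
    """A named isofunctional alternative or subunit of a step's enzyme."""

    name: str
    ec_or_koids: tuple[str, ...]
    compartment_note: str
    note: str = ""


@dataclass(frozen=True)
class PathwayStep:
    index: int
    enzyme_name: str
    ec_or_koids: tuple[str, ...]
    alternatives: tuple[EnzymeVariant, ...]
    substrate: str
    product: str
    compartment_note: str
    subunits: tuple[EnzymeVariant, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.alternatives) == 1:
            raise ValueError(
                f"step {self.enzyme_name}: alternatives must have 0 or >=2 entries"
            )
        if self.compartment_note not in COMPARTMENTS:
            raise ValueError(f"bad compartment_note {self.compartment_note!r}")
        for koid in self.all_koids():
            if not _KOID_RE.match(koid):
                raise ValueError(f"malformed KO identifier {koid!r}")

    def all_koids(self) -> tuple[str, ...]:
        """Every KO identifier attached to this step, deduplicated."""
        seen: list[str] = []
        for koid in self.ec_or_koids:
            if koid not in seen:
                seen.append(koid)
        for variant in (*self.alternatives, *self.subunits):
            for koid in variant.ec_or_koids:
                if koid not in seen:
                    seen.append(koid)
        return tuple(seen)

    def component_names(self) -> tuple[str, ...]:
        """Names a query enzyme may be assigned under (step, subunits, alts)."""
        return (
            self.enzyme_name,
            *(s.name for s in self.subunits),
            *(a.name for a in self.alternatives),
        )


@dataclass(frozen=True)
class Pathway:
    name: str
    steps: tuple[PathwayStep, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        indices = [s.index for s in self.steps]
        if indices != list(range(1, len(self.steps) + 1)):
            raise ValueError(f"pathway {self.name}: step indices not contiguous")


def _variant(d: dict) -> EnzymeVariant:
    return EnzymeVariant(
        name=d["name"],
        ec_or_koids=tuple(d.get("ec_or_koids", ())),
        compartment_note=d.get("compartment_note", "unknown"),
        note=d.get("note", ""),
    )


@lru_cache(maxsize=None)
def _load() -> dict[str, Pathway]:
    raw = json.loads(
        resources.files("plastorigin").joinpath("data/pathways.json").read_text()
    )
    pathways: dict[str, Pathway] = {}
    for name, steps in raw["pathways"].items():
        pathways[name] = Pathway(
            name=name,
            steps=tuple(
                PathwayStep(
                    index=s["index"],
                    enzyme_name=s["enzyme_name"],
                    ec_or_koids=tuple(s.get("ec_or_koids", ())),
                    alternatives=tuple(map(_variant, s.get("alternatives", ()))),
                    substrate=s["substrate"],
                    product=s["product"],
                    compartment_note=s["compartment_note"],
                    subunits=tuple(map(_variant, s.get("subunits", ()))),
                    note=s.get("note", ""),
                )
                for s in steps
            ),
        )
    return pathways


def get_pathway(name: str) -> Pathway:
    """Return one of the three registered pathways by name."""
    pathways = _load()
    if name not in pathways:
        raise KeyError(
            f"unknown pathway {name!r}; valid options: {sorted(pathways)}"
        )
    return pathways[name]


def count_steps(pathway: Pathway) -> int:
    """Number of enzymatic steps (isofunctional alternatives count once)."""
    return len(pathway.steps)


def dual_enzyme_steps(pathway: Pathway) -> list[PathwayStep]:
    """Steps catalyzed by named isofunctional enzyme variants, in step order."""
    return [s for s in pathway.steps if s.alternatives]


def find_step(pathway_name: str, enzyme: str) -> PathwayStep:
    """Locate a step by enzyme, subunit, or alternative name."""
    pathway = get_pathway(pathway_name)
    for step in pathway.steps:
        if enzyme in step.component_names():
            return step
    raise KeyError(f"no step for enzyme {enzyme!r} in pathway {pathway_name!r}")


def dump_registry(fmt: str = "tsv") -> str:
    """Flat export of the registry (``tsv`` or ``json``)."""
    if fmt == "json":
        return json.dumps(
            {
                name: [
                    {
                        "pathway": name,
                        "step_index": s.index,
                        "enzyme": s.enzyme_name,
                        "koids": list(s.all_koids()),
                        "alternatives": [a.name for a in s.alternatives],
                        "subunits": [u.name for u in s.subunits],
                        "compartment": s.compartment_note,
                    }
                    for s in get_pathway(name).steps
                ]
                for name in PATHWAY_NAMES
            },
            indent=2,
        )
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'json'")
    lines = ["pathway\tstep_index\tenzyme\tkoids\talternatives\tcompartment"]
    for name in PATHWAY_NAMES:
        for s in get_pathway(name).steps:
            lines.append(
                "\t".join(
                    [
                        name,
                        str(s.index),
                        s.enzyme_name,
                        ",".join(s.all_koids()),
                        ",".join(a.name for a in s.alternatives),
                        s.compartment_note,
                    ]
                )
            )
    return "\n".join(lines) + "\n"
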