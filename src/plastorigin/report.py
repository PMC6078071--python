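"""Aggregation of origin calls into a pathway x species x step matrix,
TSV/text rendering, and the end-to-end pipeline driver."""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassificationConfig,
    OriginCall,
    classify_all_queries,
)
from .registry import PATHWAY_NAMES, find_step
from .reconstruct import bootstrap_support
from .simulate import (
    SCENARIOS,
    ScenarioParams,
    build_scenario_tree,
    scenario_taxon_map,
    simulate_alignment,
    write_truth,
)
from .taxa import load_taxon_map
from .trees import parse_newick, write_newick

log = logging.getLogger(__name__)

CALL_TYPES = ("VI", "EA", "LA", "UNCERTAIN")

__all__ = ["StepAssignment", "OriginMatrix", "aggregate", "render", "run_pipeline"]


@dataclass(frozen=True)
class StepAssignment:
    species: str
    pathway: str
    step: str  # enzyme / subunit / alternative name


@dataclass
class OriginMatrix:
    """Call-type multiplicities per (species, pathway, step) cell.

    Cytosolic calls never enter cells; they are tallied separately.  A cell
    that exists with zero calls is distinct from an absent cell ("identified
    but unclassifiable" vs "not identified").
    """

    cells: dict[tuple[str, str, str], Counter] = field(default_factory=dict)
    cytosolic: Counter = field(default_factory=Counter)

    def cell(self, species: str, pathway: str, step: str) -> Counter:
        return self.cells.setdefault((species, pathway, step), Counter())

    def multiplicity(self, species: str, pathway: str, step: str) -> int:
        return sum(self.cells.get((species, pathway, step), Counter()).values())

    def grand_totals(self) -> Counter:
        total: Counter = Counter()
        for counter in self.cells.values():
            total.update(counter)
        return total

    @property
    def n_calls(self) -> int:
        return sum(self.grand_totals().values()) + sum(self.cytosolic.values())


def aggregate(
    calls: Sequence[OriginCall],
    assignments: dict[str, StepAssignment],
    pathway_names: Sequence[str] = PATHWAY_NAMES,
) -> OriginMatrix:
    """Fold calls into the origin matrix; order of ``calls`` is irrelevant."""
    matrix = OriginMatrix()
    for call in calls:
        if call.query_id not in assignments:
            raise KeyError(f"no step assignment for query {call.query_id!r}")
        asg = assignments[call.query_id]
        if asg.pathway not in pathway_names:
            raise KeyError(f"unknown pathway {asg.pathway!r}")
        step = find_step(asg.pathway, asg.step)  # raises on unknown step
        key = (asg.species, asg.pathway, asg.step)
        if call.cytosolic:
            matrix.cytosolic[key] += 1
            matrix.cells.setdefault(key, Counter())
            continue
        matrix.cell(*key)[call.call] += 1
        del step
    return matrix


RENDER_COLUMNS = [
    "species",
    "pathway",
    "step",
    "n_versions",
    "n_VI",
    "n_EA",
    "n_LA",
    "n_uncertain",
    "cytosolic_excluded",
]


def render(matrix: OriginMatrix, fmt: str = "tsv") -> str:
    """Render as TSV (machine-readable) or a per-pathway text grid."""
    if fmt == "tsv":
        rows = []
        for (species, pathway, step) in sorted(matrix.cells):
            counter = matrix.cells[(species, pathway, step)]
            rows.append(
                {
                    "species": species,
                    "pathway": pathway,
                    "step": step,
                    "n_versions": sum(counter.values()),
                    "n_VI": counter.get("VI", 0),
                    "n_EA": counter.get("EA", 0),
                    "n_LA": counter.get("LA", 0),
                    "n_uncertain": counter.get("UNCERTAIN", 0),
                    "cytosolic_excluded": matrix.cytosolic.get(
                        (species, pathway, step), 0
                    ),
                }
            )
        df = pd.DataFrame(rows, columns=RENDER_COLUMNS)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}; use 'tsv' or 'text'")

    symbols = {"VI": "V", "EA": "E", "LA": "L", "UNCERTAIN": "?"}
    lines = []
    pathways = sorted({p for (_, p, _) in matrix.cells})
    for pathway in pathways:
        lines.append(f"== {pathway} ==")
        keys = sorted(k for k in matrix.cells if k[1] == pathway)
        for species, _, step in keys:
            counter = matrix.cells[(species, pathway, step)]
            marks = "".join(
                symbols[c] * counter.get(c, 0) for c in CALL_TYPES
            )
            cyt = matrix.cytosolic.get((species, pathway, step), 0)
            suffix = f"  [cytosolic x{cyt}]" if cyt else ""
            lines.append(f"{species:<16s} {step:<24s} {marks or '.'}{suffix}")
    return "\n".join(lines) + "\n"


def parse_matrix_tsv(text: str) -> OriginMatrix:
    """Inverse of ``render(..., 'tsv')`` (used for round-trip checks)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    matrix = OriginMatrix()
    for _, row in df.iterrows():
        key = (str(row["species"]), str(row["pathway"]), str(row["step"]))
        counter = matrix.cell(*key)
        for call, col in (
            ("VI", "n_VI"),
            ("EA", "n_EA"),
            ("LA", "n_LA"),
            ("UNCERTAIN", "n_uncertain"),
        ):
            if int(row[col]):
                counter[call] = int(row[col])
        if int(row["cytosolic_excluded"]):
            matrix.cytosolic[key] = int(row["cytosolic_excluded"])
    return matrix


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"mode", "classify", "simulate", "reconstruct", "report"}


def _classification_config(section: dict) -> ClassificationConfig:
    known = {
        "mlbp_min",
        "bpp_min",
        "support_rule",
        "max_foreign_tips",
        "allow_exclusion_la",
        "outgroup_required",
        "long_branch_factor",
    }
    bad = set(section) - known
    if bad:
        raise ValueError(f"unknown [classify] keys: {sorted(bad)}")
    return ClassificationConfig(**section)


def _calls_frame(calls: Sequence[OriginCall], extra: dict[str, str]) -> list[dict]:
    rows = []
    for call in calls:
        rows.append(
            {
                **extra,
                "query_id": call.query_id,
                "call": call.call,
                "donor_group": call.donor_group,
                "evidence_tips": ",".join(sorted(call.evidence_clade)),
                "mlbp": (
                    "" if call.evidence_support.mlbp is None
                    else format(call.evidence_support.mlbp, "g")
                ),
                "bpp": (
                    "" if call.evidence_support.bpp is None
                    else format(call.evidence_support.bpp, "g")
                ),
                "exclusion_based": call.exclusion_based,
                "cytosolic": call.cytosolic,
                "notes": call.notes,
            }
        )
    return rows


def run_pipeline(config: Union[str, Path, dict], outdir: Union[str, Path]) -> dict:
    """Run simulate -> reconstruct -> classify -> report from one config.

    Synthetic mode generates gene families with known truth and reports
    per-scenario recovery; real mode classifies user-supplied trees.
    Returns a summary dict; artifacts are written under ``outdir``.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        config = yaml.safe_load(config_path.read_text())
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    mode = config.get("mode")
    if mode not in ("synthetic", "real"):
        raise ValueError("config key 'mode' must be 'synthetic' or 'real'")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _classification_config(config.get("classify", {}) or {})
    log_lines = [f"plastorigin {__version__}", f"mode: {mode}", f"config: {config}"]

    call_rows: list[dict] = []
    summary: dict = {"mode": mode}

    if mode == "synthetic":
        sim = dict(config.get("simulate", {}) or {})
        recon = dict(config.get("reconstruct", {}) or {})
        scenarios = sim.pop("scenarios", list(SCENARIOS))
        reps = int(sim.pop("reps", 1))
        base_seed = int(sim.pop("seed", 0))
        length = int(sim.pop("length", 500))
        bootstrap = int(recon.pop("bootstrap", 100))
        if recon:
            raise ValueError(f"unknown [reconstruct] keys: {sorted(recon)}")
        donor_spec = sim.pop("donor_groups", None)
        if donor_spec is not None:
            sim["donor_groups"] = tuple(
                (str(name), int(size)) for name, size in donor_spec
            )
        recovery: dict[str, Counter] = {s: Counter() for s in scenarios}
        for scenario in scenarios:
            for rep in range(reps):
                seed = base_seed + 1000 * SCENARIOS.index(scenario) + rep
                params = ScenarioParams(scenario=scenario, seed=seed, **sim)
                tree, truth = build_scenario_tree(params)
                tmap = scenario_taxon_map(params)
                msa = simulate_alignment(tree, length, seed=seed + 7)
                inferred = bootstrap_support(msa, B=bootstrap, seed=seed + 13)
                call = classify_all_queries(
                    inferred, [truth.query_id], tmap, cfg
                )[0]
                ok = call.call == scenario
                recovery[scenario][
                    "correct" if ok else (
                        "uncertain" if call.call == "UNCERTAIN" else "incorrect"
                    )
                ] += 1
                call_rows.extend(
                    _calls_frame(
                        [call],
                        {"family": f"{scenario}_rep{rep}", "truth": scenario},
                    )
                )
                log_lines.append(
                    f"{scenario} rep {rep} seed {seed}: called {call.call} "
                    f"({call.notes})"
                )
        rec_rows = [
            {
                "scenario": s,
                "correct": c.get("correct", 0),
                "incorrect": c.get("incorrect", 0),
                "uncertain": c.get("uncertain", 0),
            }
            for s, c in recovery.items()
        ]
        pd.DataFrame(rec_rows).to_csv(
            outdir / "recovery_summary.tsv", sep="\t", index=False
        )
        summary["recovery"] = {
            s: dict(c) for s, c in recovery.items()
        }
    else:
        families = config.get("report", {}).get("families")
        if not families:
            raise ValueError("real mode needs [report] families entries")
        calls_with_assignments: list[OriginCall] = []
        assignments: dict[str, StepAssignment] = {}
        for fam in families:
            needed = {"tree", "taxa", "queries"} - set(fam)
            if needed:
                raise ValueError(f"family entry missing keys: {sorted(needed)}")
            tree = parse_newick(Path(fam["tree"]).read_text())
            tmap = load_taxon_map(fam["taxa"], fam.get("roles"))
            queries = list(fam["queries"])
            try:
                calls = classify_all_queries(tree, queries, tmap, cfg)
            except (ValueError, KeyError) as exc:
                log_lines.append(f"family {fam['tree']}: FAILED ({exc})")
                continue
            call_rows.extend(_calls_frame(calls, {"family": str(fam["tree"])}))
            asg = fam.get("assignment")
            if asg:
                for call in calls:
                    assignments[call.query_id] = StepAssignment(
                        species=asg["species"],
                        pathway=asg["pathway"],
                        step=asg["step"],
                    )
                    calls_with_assignments.append(call)
        if calls_with_assignments:
            matrix = aggregate(calls_with_assignments, assignments)
            (outdir / "matrix.tsv").write_text(render(matrix, "tsv"))
            summary["matrix_cells"] = len(matrix.cells)

    df = pd.DataFrame(call_rows)
    df.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    summary["n_calls"] = len(call_rows)
    return summary


def write_synthetic_family(
    params: ScenarioParams, length: int, out_prefix: Union[str, Path]
) -> None:
    """Emit fam.true.nwk / fam.fasta / fam.taxa.tsv / fam.truth.json."""
    from .alignment import write_fasta
    from .taxa import write_taxon_map

    prefix = str(out_prefix)
    tree, truth = build_scenario_tree(params)
    msa = simulate_alignment(tree, length, seed=params.seed + 7)
    Path(prefix + ".true.nwk").write_text(write_newick(tree) + "\n")
    write_fasta(msa, prefix + ".fasta")
    write_taxon_map(scenario_taxon_map(params), prefix + ".taxa.tsv")
    write_truth(truth, prefix + ".truth.json")
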