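"""N-terminal extension detection against bacterial reference homologs.

A query's extension is the run of its residues aligned strictly before the
reference start column, where the reference start is the lower median of the
first non-gap columns of the designated reference rows (robust to a single
aberrant homolog).  Signal-peptide (SP) and transit-peptide (TP) predictions
are ingested from an external table and follow a conditional order: the TP
verdict is meaningful only when an SP was predicted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .alignment import GAP, MSA

log = logging.getLogger(__name__)

__all__ = [
    "ExtensionReport",
    "reference_start_column",
    "detect_extension",
    "load_predictions",
    "merge_external_predictions",
]

DEFAULT_MIN_LEN = 10


@dataclass(frozen=True)
class ExtensionReport:
    query_id: str
    extension_length: int
    has_extension: bool
    sp_predicted: Optional[bool] = None  # None means unknown
    tp_predicted: Optional[bool] = None
    reference_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.extension_length < 0:
            raise ValueError("extension_length must be >= 0")
        if self.tp_predicted is not None and self.sp_predicted is not True:
            raise ValueError(
                "tp_predicted may only be set when sp_predicted is True"
            )


def _first_residue_column(msa: MSA, seq_id: str) -> int:
    row = msa[seq_id]
    for col, char in enumerate(row):
        if char != GAP:
            return col
    raise ValueError(f"sequence {seq_id!r} is entirely gaps")


def reference_start_column(msa: MSA, reference_ids: Sequence[str]) -> int:
    """Lower-median first non-gap column over the reference rows (0-based)."""
    if not reference_ids:
        raise ValueError("need at least one reference id")
    starts = sorted(_first_residue_column(msa, r) for r in reference_ids)
    return starts[(len(starts) - 1) // 2]


def detect_extension(
    msa: MSA,
    query_id: str,
    reference_ids: Sequence[str],
    min_len: int = DEFAULT_MIN_LEN,
) -> ExtensionReport:
    """Count query residues before the reference start column."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    start = reference_start_column(msa, reference_ids)
    row = msa[query_id]
    _first_residue_column(msa, query_id)  # reject all-gap queries
    length = sum(1 for char in row[:start] if char != GAP)
    return ExtensionReport(
        query_id=query_id,
        extension_length=length,
        has_extension=length >= min_len,
        reference_ids=tuple(reference_ids),
    )


def load_predictions(path: Union[str, Path]) -> pd.DataFrame:
    """Read an SP/TP prediction table: columns ``id``, ``sp``, ``tp``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"id", "sp", "tp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prediction TSV missing columns {sorted(missing)}")

    def to_bool(x: str) -> bool:
        if str(x).strip().lower() in ("1", "true", "yes", "y"):
            return True
        if str(x).strip().lower() in ("0", "false", "no", "n"):
            return False
        raise ValueError(f"{path}: non-boolean prediction value {x!r}")

    df["sp"] = df["sp"].map(to_bool)
    df["tp"] = df["tp"].map(to_bool)
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate prediction ids {dup}")
    return df


def merge_external_predictions(
    report: ExtensionReport, preds: pd.DataFrame
) -> ExtensionReport:
    """Fill SP/TP fields from an external prediction table.

    A TP prediction without a preceding SP prediction is discarded (stored as
    unknown) with a warning; a query absent from the table is left untouched.
    """
    hit = preds.loc[preds["id"] == report.query_id]
    if hit.empty:
        return report
    sp = bool(hit.iloc[0]["sp"])
    tp = bool(hit.iloc[0]["tp"])
    if not sp:
        if tp:
            msg = (
                f"{report.query_id}: TP predicted without SP; TP stored as "
                "unknown (SP-then-TP order)"
            )
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
        return replace(report, sp_predicted=False, tp_predicted=None)
    return replace(report, sp_predicted=True, tp_predicted=tp)


def summarize(reports: Sequence[ExtensionReport]) -> dict[str, int]:
    """Counts in the shape "N of M bear extensions; S have SP; K have SP+TP"."""
    n_total = len(reports)
    with_ext = [r for r in reports if r.has_extension]
    with_sp = [r for r in with_ext if r.sp_predicted is True]
    with_sp_tp = [r for r in with_sp if r.tp_predicted is True]
    return {
        "total": n_total,
        "with_extension": len(with_ext),
        "with_sp": len(with_sp),
        "with_sp_and_tp": len(with_sp_tp),
    }
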