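"""Minimal protein multiple-alignment container with FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

__all__ = ["AMINO_ACIDS", "GAP", "MSA", "read_fasta", "write_fasta"]


@dataclass(frozen=True)
class MSA:
    """Aligned amino-acid rows keyed by id; all rows have equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def __getitem__(self, key: str) -> str:
        if key not in self.rows:
            raise KeyError(f"sequence {key!r} not in alignment")
        return self.rows[key]

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    def __len__(self) -> int:
        return len(self.rows)


def read_fasta(path: Union[str, Path]) -> MSA:
    rows: dict[str, str] = {}
    current: list[str] = []
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                rows[name] = "".join(current)
            name = line[1:].split()[0]
            if name in rows:
                raise ValueError(f"{path}: duplicate sequence id {name!r}")
            current = []
        else:
            if name is None:
                raise ValueError(f"{path}: sequence data before first header")
            current.append(line)
    if name is not None:
        rows[name] = "".join(current)
    return MSA(rows)


def write_fasta(msa: MSA, path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.rows.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
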