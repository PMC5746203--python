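"""Mouse-probe -> mouse-gene -> human-gene -> human-probe orthology tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["OrthologyMap"]

COLUMNS = ["mouse_probe", "mouse_gene", "human_gene", "human_probe"]


@dataclass
class OrthologyMap:
    """Many-to-many orthology relation used to transfer a mouse probe
    signature onto human array probes.

    Each row links one mouse probe, via its gene and the human orthologue
    gene, to one human probe.  A mouse gene may be covered by several
    probes, a human gene by several probes, and a mouse gene without a
    human orthologue simply has no rows.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"orthology table lacks columns {missing}")
        self.table = self.table[COLUMNS].astype(str).reset_index(drop=True)
        if self.table.duplicated().any():
            raise ValueError("duplicate orthology rows")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologyMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))
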