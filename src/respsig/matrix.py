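"""Probe-by-sample expression matrices.

The :class:`ExpressionMatrix` is the substrate of every pipeline stage: a
real-valued probe x sample matrix, optionally paired with a same-shaped
matrix of bead-array detection p-values (the per-cell probability that the
measured signal is indistinguishable from background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Expression values indexed by probe (rows) and sample (columns).

    Parameters
    ----------
    values : pandas.DataFrame
        Intensities (raw scale) or variance-stabilized expression
        (transform units); index = probe ids, columns = sample ids.
    detection_p : pandas.DataFrame, optional
        Per-cell detection p-values in [0, 1], same shape and labels as
        ``values``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.detection_p is not None:
            dp = self.detection_p
            if dp.shape != self.values.shape:
                raise ValueError(
                    "detection_p shape %s does not match values shape %s"
                    % (dp.shape, self.values.shape)
                )
            # align labels strictly; reorder rather than trust positional identity
            if not dp.index.equals(self.values.index) or not dp.columns.equals(
                self.values.columns
            ):
                self.detection_p = dp.loc[self.values.index, self.values.columns]
            bad = self.detection_p.to_numpy()
            if np.any((bad < 0) | (bad > 1)):
                raise ValueError("detection p-values must lie in [0, 1]")

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "ExpressionMatrix":
        """Return a copy restricted to ``probes`` (original row order kept)."""
        keep = self.values.index.isin(set(probes))
        return ExpressionMatrix(
            self.values.loc[keep].copy(),
            None if self.detection_p is None else self.detection_p.loc[keep].copy(),
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples].copy(),
            None if self.detection_p is None else self.detection_p[samples].copy(),
        )

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV (first column ``probe_id``); detection
        p-values, if present, go to a sibling file with suffix ``.detp.tsv``."""
        path = Path(path)
        out = self.values.copy()
        out.insert(0, "probe_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        if self.detection_p is not None:
            dp = self.detection_p.copy()
            dp.insert(0, "probe_id", dp.index)
            dp.to_csv(
                path.with_suffix(path.suffix + ".detp.tsv")
                if path.suffix != ".tsv"
                else path.with_name(path.name[: -len(".tsv")] + ".detp.tsv"),
                sep="\t",
                index=False,
                float_format="%.10g",
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="probe_id")
        values.index = values.index.astype(str)
        detp_path = (
            path.with_name(path.name[: -len(".tsv")] + ".detp.tsv")
            if path.name.endswith(".tsv")
            else path.with_suffix(path.suffix + ".detp.tsv")
        )
        detection_p = None
        if detp_path.exists():
            detection_p = pd.read_csv(detp_path, sep="\t", index_col="probe_id")
            detection_p.index = detection_p.index.astype(str)
        return cls(values, detection_p)
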