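"""Bead-array preprocessing: detection filtering, variance-stabilizing
transform, variance filtering, batch adjustment, and phenotype outlier
exclusion.

The canonical ordering, fixed because the variance filter's reference
point (the maximum per-probe standard deviation) depends on the current
matrix, is::

    detection_filter -> vst_transform -> variance_filter

Each filter is idempotent on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "DetectionRule",
    "MOUSE_DETECTION_RULE",
    "HUMAN_DETECTION_RULE",
    "detection_filter",
    "vst_transform",
    "inverse_vst",
    "variance_filter",
    "batch_adjust",
    "exclude_outliers_95",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionRule:
    """Retain probes detected (p < alpha) in enough samples.

    Exactly one of ``min_samples`` (absolute count) and ``min_fraction``
    (proportion of samples, rounded up) must be set.
    """

    alpha: float
    min_samples: int | None = None
    min_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if (self.min_samples is None) == (self.min_fraction is None):
            raise ValueError("set exactly one of min_samples and min_fraction")
        if self.min_samples is not None and self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_fraction is not None and not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")

    def required_samples(self, n_samples: int) -> int:
        if self.min_samples is not None:
            return self.min_samples
        return ceil(self.min_fraction * n_samples)


#: blood/brain bead-array rule: detected at p < 0.05 in at least 4 samples
MOUSE_DETECTION_RULE = DetectionRule(alpha=0.05, min_samples=4)
#: human HT-12 rule: detected at p < 0.01 in at least 10 % of samples
HUMAN_DETECTION_RULE = DetectionRule(alpha=0.01, min_fraction=0.10)


def detection_filter(matrix: ExpressionMatrix, rule: DetectionRule) -> ExpressionMatrix:
    """Retain probes whose detection p-value is below ``rule.alpha`` in at
    least the required number of samples; probe order and samples are
    unchanged."""
    if matrix.detection_p is None:
        raise ValueError("detection_filter requires detection p-values")
    need = rule.required_samples(matrix.n_samples)
    detected = (matrix.detection_p.to_numpy() < rule.alpha).sum(axis=1)
    keep = detected >= need
    logger.info(
        "detection_filter: %d of %d probes retained (p < %g in >= %d samples)",
        int(keep.sum()), matrix.n_probes, rule.alpha, need,
    )
    return ExpressionMatrix(
        matrix.values.loc[keep].copy(), matrix.detection_p.loc[keep].copy()
    )


def vst_transform(matrix: ExpressionMatrix, c: float | None = None) -> ExpressionMatrix:
    """Generalized-log variance-stabilizing transform.

    Applies ``x -> log2((x + sqrt(x^2 + c^2)) / 2)`` elementwise.  The
    transform is strictly increasing, behaves like log2(x) for x >> c and
    is linear near zero, flattening the variance of data whose noise
    scales with intensity.  ``c`` defaults to the median raw intensity.
    """
    x = matrix.values.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("raw intensities must be >= 0")
    if c is None:
        c = float(np.median(x))
        if c <= 0:
            raise ValueError("median intensity is not positive; pass c explicitly")
    if c <= 0:
        raise ValueError("c must be > 0")
    y = np.log2((x + np.sqrt(x * x + c * c)) / 2.0)
    return ExpressionMatrix(
        pd.DataFrame(y, index=matrix.probe_ids, columns=matrix.sample_ids),
        None if matrix.detection_p is None else matrix.detection_p.copy(),
    )


def inverse_vst(matrix: ExpressionMatrix, c: float) -> ExpressionMatrix:
    """Exact inverse of :func:`vst_transform`: ``y -> 2^y - c^2 / 2^(y+2)``."""
    if c <= 0:
        raise ValueError("c must be > 0")
    v = np.exp2(matrix.values.to_numpy(dtype=float))
    x = v - (c * c) / (4.0 * v)
    return ExpressionMatrix(
        pd.DataFrame(x, index=matrix.probe_ids, columns=matrix.sample_ids),
        None if matrix.detection_p is None else matrix.detection_p.copy(),
    )


def variance_filter(matrix: ExpressionMatrix, threshold_fraction: float = 0.05) -> ExpressionMatrix:
    """Retain probes whose standard deviation is at least
    ``threshold_fraction`` of the largest per-probe standard deviation in
    the current matrix (the relative-variance slider of array-QC tools)."""
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1]")
    if matrix.n_samples < 2:
        raise ValueError("variance_filter needs >= 2 samples")
    sds = matrix.values.to_numpy().std(axis=1, ddof=1)
    cutoff = threshold_fraction * sds.max() if len(sds) else 0.0
    keep = sds >= cutoff
    logger.info(
        "variance_filter: %d of %d probes retained (sd >= %.3g)",
        int(keep.sum()), matrix.n_probes, cutoff,
    )
    return ExpressionMatrix(
        matrix.values.loc[keep].copy(),
        None if matrix.detection_p is None else matrix.detection_p.loc[keep].copy(),
    )


def batch_adjust(matrix: ExpressionMatrix, batch_labels) -> ExpressionMatrix:
    """Per-probe location/scale batch correction.

    Within each batch, values are centered to the probe's grand mean and
    rescaled so every batch's variance matches the pooled within-batch
    variance.  A batch of one sample cannot be adjusted and is an error.
    """
    labels = pd.Series(list(batch_labels), index=matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a batch label")
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"batches with a single sample: {sorted(singletons.index)}")

    x = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(x)
    grand = x.mean(axis=1, keepdims=True)
    batches = {b: np.where((labels == b).to_numpy())[0] for b in counts.index}
    # pooled within-batch variance, df-weighted
    ss = np.zeros(x.shape[0])
    df = 0
    for idx in batches.values():
        sub = x[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    pooled_sd = np.sqrt(ss / max(df, 1))
    for idx in batches.values():
        sub = x[:, idx]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1)
        scale = np.where(sd > 0, pooled_sd / np.where(sd > 0, sd, 1.0), 1.0)
        out[:, idx] = (sub - mu) * scale[:, None] + grand
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids),
        None if matrix.detection_p is None else matrix.detection_p.copy(),
    )


def exclude_outliers_95(values) -> tuple[np.ndarray, np.ndarray]:
    """Split phenotype measurements into retained values and the indices
    of values outside mean ± 1.96 sd of the input (population sd: the
    sample itself defines the tolerance band)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    mu, sd = arr.mean(), arr.std(ddof=0)
    lo, hi = mu - 1.96 * sd, mu + 1.96 * sd
    outside = np.where((arr < lo) | (arr > hi))[0]
    retained = arr[(arr >= lo) & (arr <= hi)]
    return retained, outside
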