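"""Covariate-adjusted two-group differential expression.

The model is per-probe ordinary least squares of transformed expression
on a two-level group indicator plus nuisance covariates (bead-chip /
amplification batch as categorical terms, drug concentration as a
continuous term)::

    y_probe = b0 + b_g * group + sum_j c_j * covariate_j + e

Inference on the group coefficient (a t-test, identical to the two-level
ANOVA F-test) yields per-probe p-values; the Benjamini-Hochberg step-up
procedure converts them to FDR q-values, from which signatures are
selected at q < 0.1 (discovery) and q < 0.05 (stringent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

from .matrix import ExpressionMatrix

__all__ = [
    "DesignSpec",
    "ProbewiseDE",
    "DEResults",
    "CrossTissueTable",
    "bh_adjust",
    "select_signature",
    "volcano_table",
    "cross_tissue_pattern",
]


@dataclass(frozen=True)
class DesignSpec:
    """Two-group contrast with optional nuisance covariates.

    ``group`` names an annotation column; ``levels`` gives the two levels
    to contrast (effect = second minus first).
    """

    group: str
    levels: tuple[str, str]
    categorical_covariates: tuple[str, ...] = ()
    continuous_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.levels) != 2 or self.levels[0] == self.levels[1]:
            raise ValueError("exactly 2 distinct group levels required")


def _build_design(annotation: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + dummy-coded categorical covariates +
    centered continuous covariates."""
    cols: list[np.ndarray] = [np.ones(len(annotation))]
    names = ["intercept"]
    grp = annotation[design.group].to_numpy()
    cols.append((grp == design.levels[1]).astype(float))
    names.append(f"{design.group}[{design.levels[1]}]")
    for cov in design.categorical_covariates:
        values = annotation[cov].astype(str).to_numpy()
        levels = sorted(set(values))
        for lv in levels[1:]:  # first level is the reference
            cols.append((values == lv).astype(float))
            names.append(f"{cov}[{lv}]")
    for cov in design.continuous_covariates:
        v = annotation[cov].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"continuous covariate {cov} has missing values")
        cols.append(v - v.mean())
        names.append(cov)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise on rank deficiency, naming aliased columns."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    aliased = []
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            aliased.append(names[j])
    raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


class ProbewiseDE:
    """Per-probe two-group OLS model over an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Preprocessed (transformed, filtered) expression.
    annotation : pandas.DataFrame
        One row per sample; must contain the design's group and covariate
        columns plus a sample-id column matching the matrix.
    design : DesignSpec
    sample_id_col : str, optional
        Defaults to the first of ``animal_id``, ``patient_id``,
        ``sample_id`` present.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: pd.DataFrame,
        design: DesignSpec,
        sample_id_col: str | None = None,
    ) -> None:
        if sample_id_col is None:
            for cand in ("animal_id", "patient_id", "sample_id"):
                if cand in annotation.columns:
                    sample_id_col = cand
                    break
            else:
                raise ValueError("no sample id column found in annotation")
        ann = annotation.set_index(sample_id_col, drop=False)
        keep = ann[ann[design.group].isin(design.levels)]
        for lv in design.levels:
            if (keep[design.group] == lv).sum() < 2:
                raise ValueError(f"group level {lv!r} has fewer than 2 samples")
        self.design = design
        self.annotation = keep
        self.matrix = matrix.subset_samples(keep.index)

    def fit(self) -> "DEResults":
        X, names = _build_design(self.annotation, self.design)
        _check_rank(X, names)
        Y = self.matrix.values.to_numpy(dtype=float)  # probes x samples
        n, p = X.shape
        df_resid = n - p

        pinv = np.linalg.pinv(X)
        beta = Y @ pinv.T  # probes x p
        resid = Y - beta @ X.T
        rss = (resid**2).sum(axis=1)

        effect = beta[:, 1].copy()
        degenerate = np.zeros(len(effect), dtype=bool)
        pvals = np.ones(len(effect))
        se = np.full(len(effect), np.nan)
        if df_resid <= 0:
            degenerate[:] = True
        else:
            sigma2 = rss / df_resid
            xtx_inv_gg = np.linalg.inv(X.T @ X)[1, 1]
            se = np.sqrt(sigma2 * xtx_inv_gg)
            ok = se > 1e-12
            degenerate = ~ok
            t = np.zeros(len(effect))
            t[ok] = effect[ok] / se[ok]
            pvals[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df_resid)
        effect[degenerate & (np.abs(effect) < 1e-10)] = 0.0

        stats = pd.DataFrame(
            {
                "probe_id": self.matrix.probe_ids,
                "effect": effect,
                "se": se,
                "sign": np.sign(effect).astype(int),
                "p": pvals,
                "degenerate": degenerate,
            }
        ).reset_index(drop=True)
        stats["q"] = bh_adjust(stats["p"].to_numpy())
        return DEResults(stats=stats, design=self.design, df_resid=df_resid, term_names=names)


@dataclass
class DEResults:
    """Per-probe differential-expression statistics with BH q-values."""

    stats: pd.DataFrame
    design: DesignSpec
    df_resid: int
    term_names: list[str] = field(default_factory=list)

    def select_signature(self, q_threshold: float) -> pd.DataFrame:
        return select_signature(self.stats, q_threshold)

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.stats)

    def summary(self) -> str:
        s = self.stats
        lines = [
            "Probewise differential expression (OLS, two-group contrast)",
            "=" * 60,
            f"contrast:        {self.design.group} "
            f"({self.design.levels[1]} - {self.design.levels[0]})",
            f"covariates:      {list(self.design.categorical_covariates) + list(self.design.continuous_covariates) or 'none'}",
            f"probes tested:   {len(s)}",
            f"residual df:     {self.df_resid}",
            f"degenerate:      {int(s['degenerate'].sum())}",
            f"q < 0.10:        {int((s['q'] < 0.10).sum())}",
            f"q < 0.05:        {int((s['q'] < 0.05).sum())}",
            f"min q:           {s['q'].min():.3g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.stats[["probe_id", "effect", "sign", "p", "q"]].to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


# ----------------------------------------------------------------------
def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the ascending order
    statistics, capped at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def select_signature(stats: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    """Probes with q below threshold, with effect signs, ordered by
    ascending q then probe id (deterministic)."""
    if "q" not in stats.columns:
        raise ValueError("q-values not filled")
    hits = stats[stats["q"] < q_threshold]
    return (
        hits.sort_values(["q", "probe_id"], kind="stable")[["probe_id", "effect", "sign", "q"]]
        .reset_index(drop=True)
    )


_TINY_Q = np.finfo(float).tiny


def volcano_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-probe (effect, -log10 q) pairs for volcano plotting; q = 0 is
    floored at the smallest positive float."""
    q = np.maximum(stats["q"].to_numpy(dtype=float), _TINY_Q)
    return pd.DataFrame(
        {
            "probe_id": stats["probe_id"],
            "effect": stats["effect"],
            "neg_log10_q": -np.log10(q),
        }
    ).reset_index(drop=True)


@dataclass
class CrossTissueTable:
    """Blood-vs-brain per-probe expression differences for the signature,
    ordered by complete-linkage hierarchical clustering."""

    table: pd.DataFrame  # probe_id, delta_blood, delta_brain
    row_order: np.ndarray
    correlation: float

    def ordered(self) -> pd.DataFrame:
        return self.table.iloc[self.row_order].reset_index(drop=True)


def cross_tissue_pattern(
    blood_stats: pd.DataFrame, brain_stats: pd.DataFrame, signature
) -> CrossTissueTable:
    """Compare good-vs-poor expression differences across tissues.

    Signature probes missing (or degenerate/NaN) in either tissue are
    dropped; the remaining two-column difference matrix is ordered by
    agglomerative complete-linkage clustering with Euclidean distances,
    and the blood-brain correlation of the differences is reported.
    """
    sig = list(signature)
    blood = blood_stats.set_index("probe_id")["effect"]
    brain = brain_stats.set_index("probe_id")["effect"]
    missing_in_blood = [p for p in sig if p not in blood.index]
    if missing_in_blood:
        raise ValueError(f"signature probes absent from blood stats: {missing_in_blood[:5]}")
    rows = []
    for probe in sig:
        if probe in brain.index:
            db, dr = blood.loc[probe], brain.loc[probe]
            if np.isfinite(db) and np.isfinite(dr):
                rows.append((probe, float(db), float(dr)))
    if len(rows) < 2:
        raise ValueError("fewer than 2 signature probes measured in both tissues")
    table = pd.DataFrame(rows, columns=["probe_id", "delta_blood", "delta_brain"])
    X = table[["delta_blood", "delta_brain"]].to_numpy()
    Z = linkage(X, method="complete", metric="euclidean")
    row_order = np.asarray(leaves_list(Z))
    if np.std(X[:, 0]) == 0 or np.std(X[:, 1]) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
    return CrossTissueTable(table=table, row_order=row_order, correlation=corr)
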