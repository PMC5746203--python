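"""Phenotyping: extreme-group stratification of treated mice, human
response labelling from HDRS-17 change, and the drug-concentration
covariate (imputation and correlation)."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

__all__ = [
    "stratify_extremes",
    "label_response",
    "impute_plasma_from_brain",
    "pearson_r",
]

logger = logging.getLogger(__name__)


def stratify_extremes(annotation: pd.DataFrame, fraction: float = 0.20) -> pd.DataFrame:
    """Label treated animals as good / poor responders by floating time.

    Among ``arm == "paroxetine"`` animals only, the ``k = floor(fraction * n)``
    with the lowest forced-swim-test floating time become ``good``, the k
    highest become ``poor``, and the rest ``intermediate``.  Ties are
    broken by stable ``animal_id`` order.  Vehicle animals keep the label
    ``vehicle``.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    out = annotation.copy()
    treated = out[out["arm"] == "paroxetine"]
    if treated["floating_s"].isna().any():
        raise ValueError("treated animals must have floating times")
    n = len(treated)
    k = math.floor(fraction * n)
    if k == 0:
        raise ValueError(f"fraction {fraction} of {n} treated animals selects no extremes")
    if n < 2 * k:
        raise ValueError("extreme groups would overlap (n < 2k)")
    ranked = treated.sort_values(["floating_s", "animal_id"], kind="stable")
    good_ids = set(ranked["animal_id"].iloc[:k])
    poor_ids = set(ranked["animal_id"].iloc[-k:])
    labels = np.where(
        out["animal_id"].isin(good_ids),
        "good",
        np.where(out["animal_id"].isin(poor_ids), "poor", "intermediate"),
    )
    out["responder"] = np.where(out["arm"] == "paroxetine", labels, "vehicle")
    logger.info("stratify_extremes: %d good, %d poor of %d treated animals", k, k, n)
    return out


def label_response(annotation: pd.DataFrame, threshold: float = 50.0) -> pd.DataFrame:
    """Fill ``pct_change`` and boolean ``responder`` from HDRS-17 scores.

    Response is at least a ``threshold`` % improvement (default 50) from
    baseline to week 12: ``pct_change = 100 * (baseline - week12) /
    baseline``, responder iff pct_change >= threshold.  Score worsening
    gives a negative change and a nonresponder label.
    """
    out = annotation.copy()
    zero = out[out["hdrs_baseline"] <= 0]
    if len(zero):
        raise ValueError(
            f"hdrs_baseline must be > 0; offending patients: {list(zero['patient_id'])}"
        )
    out["pct_change"] = 100.0 * (out["hdrs_baseline"] - out["hdrs_week12"]) / out["hdrs_baseline"]
    out["responder"] = out["pct_change"] >= threshold
    logger.info(
        "label_response: %d responders, %d nonresponders",
        int(out["responder"].sum()), int((~out["responder"]).sum()),
    )
    return out


def impute_plasma_from_brain(annotation: pd.DataFrame) -> pd.DataFrame:
    """Complete missing plasma drug concentrations from brain concentrations.

    Fits ordinary least squares ``plasma = a + b * brain`` on animals with
    both measurements and fills each missing plasma value with its fitted
    value.  Animals missing both concentrations are an error.
    """
    out = annotation.copy()
    has_p = out["plasma_conc"].notna()
    has_b = out["brain_conc"].notna()
    need = ~has_p
    orphans = out[need & ~has_b]
    if len(orphans):
        raise ValueError(
            f"animals missing both concentrations: {list(orphans['animal_id'])}"
        )
    complete = out[has_p & has_b]
    if len(complete) < 2:
        raise ValueError("need >= 2 animals with both concentrations to fit the regression")
    b_arr = complete["brain_conc"].to_numpy(dtype=float)
    p_arr = complete["plasma_conc"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(b_arr, p_arr, 1)
    fitted = intercept + slope * b_arr
    ss_res = float(((p_arr - fitted) ** 2).sum())
    ss_tot = float(((p_arr - p_arr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n_fill = int(need.sum())
    out.loc[need, "plasma_conc"] = intercept + slope * out.loc[need, "brain_conc"]
    logger.info(
        "impute_plasma_from_brain: filled %d values; plasma = %.4g + %.4g * brain (r2 = %.3f)",
        n_fill, intercept, slope, r2,
    )
    out.attrs["plasma_imputation"] = {
        "intercept": float(intercept), "slope": float(slope), "r2": r2, "n_imputed": n_fill,
    }
    return out


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal lengths >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])
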