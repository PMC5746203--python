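"""Dexamethasone-regulation enrichment of the response signature.

Within the "common content" (the intersection of probe ids measured on
two independent arrays), the overlap of the response signature with the
dexamethasone-regulated probe set is referred to three complementary
references:

* a Monte-Carlo null of random size-matched probe sets (strictly-greater
  exceedance, add-one p-value);
* the exact upper-tail hypergeometric probability of the 2x2 overlap
  table; and
* an exact binomial test of directional concordance between the
  signature's effect signs and the dexamethasone regulation signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

__all__ = [
    "OverlapTable",
    "EnrichmentResult",
    "DexEnrichment",
    "build_common_content",
    "overlap_table",
    "hypergeometric_pvalue",
    "permutation_enrichment",
    "direction_concordance",
    "binomial_direction_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapTable:
    """2x2 contingency table of signature membership vs dex regulation
    over a probe universe of size N."""

    N: int  # universe (common content) size
    K: int  # dex-regulated probes within the universe
    n: int  # signature probes within the universe
    k: int  # overlap

    def __post_init__(self) -> None:
        cells = self.cells
        if any(c < 0 for c in cells):
            raise ValueError(f"negative contingency cell in {cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.k, self.n - self.k, self.K - self.k, self.N - self.K - self.n + self.k)


def build_common_content(universe_a, universe_b) -> list[str]:
    """Exact probe-id intersection of two array universes, sorted."""
    common = sorted(set(map(str, universe_a)) & set(map(str, universe_b)))
    if not common:
        raise ValueError("the two probe universes do not intersect")
    return common


def overlap_table(signature, dex_set, universe) -> OverlapTable:
    sig = set(map(str, signature))
    dex = set(map(str, dex_set))
    uni = set(map(str, universe))
    if not sig <= uni:
        raise ValueError("signature is not a subset of the universe")
    if not dex <= uni:
        raise ValueError("dex set is not a subset of the universe")
    return OverlapTable(N=len(uni), K=len(dex), n=len(sig), k=len(sig & dex))


def hypergeometric_pvalue(table: OverlapTable) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if table.k == 0:
        return 1.0
    return float(sps.hypergeom.sf(table.k - 1, table.N, table.K, table.n))


def permutation_enrichment(
    n: int,
    dex_set,
    universe,
    observed_k: int,
    m: int = 100_000,
    seed: int = 0,
    comparison: str = "greater",
) -> dict:
    """Monte-Carlo overlap null: m uniform without-replacement draws of
    size n from the universe, counting draws whose dex overlap exceeds
    the observed one (strictly greater by default)."""
    universe = sorted(map(str, universe))
    dex = set(map(str, dex_set))
    if not dex <= set(universe):
        raise ValueError("dex set is not a subset of the universe")
    N = len(universe)
    if n > N:
        raise ValueError("signature size exceeds the universe")
    if comparison not in ("greater", "greater_equal"):
        raise ValueError("comparison must be 'greater' or 'greater_equal'")
    is_dex = np.fromiter((p in dex for p in universe), dtype=bool, count=N)
    rng = np.random.default_rng(seed)

    # batched random subsets: the n smallest of N iid uniform keys are a
    # uniform without-replacement sample
    overlaps = np.empty(m, dtype=np.int64)
    chunk = max(1, min(m, int(4e7 // max(N, 1))))
    done = 0
    while done < m:
        b = min(chunk, m - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        overlaps[done : done + b] = is_dex[idx].sum(axis=1)
        done += b
    if comparison == "greater":
        exceed = int((overlaps > observed_k).sum())
    else:
        exceed = int((overlaps >= observed_k).sum())
    return {
        "m": m,
        "exceedances": exceed,
        "p_perm": (exceed + 1) / (m + 1),
        "mean_null_overlap": float(overlaps.mean()),
        "null_overlaps": overlaps,
        "seed": seed,
        "comparison": comparison,
    }


def direction_concordance(
    signature_signs: Mapping[str, int],
    dex_signs: Mapping[str, int],
    overlap,
) -> tuple[int, int]:
    """Count overlap probes regulated in the same vs opposite direction.

    Probes with a zero sign on either side carry no direction and are
    excluded (logged); a probe missing from either sign map is an error.
    """
    n_same = n_mismatch = n_zero = 0
    for probe in map(str, overlap):
        if probe not in signature_signs:
            raise ValueError(f"no signature sign for probe {probe}")
        if probe not in dex_signs:
            raise ValueError(f"no dex sign for probe {probe}")
        a, b = signature_signs[probe], dex_signs[probe]
        if a == 0 or b == 0:
            n_zero += 1
        elif a == b:
            n_same += 1
        else:
            n_mismatch += 1
    if n_zero:
        logger.info("direction_concordance: %d probes with zero sign excluded", n_zero)
    return n_same, n_mismatch


def binomial_direction_test(
    n_same: int, n_total: int, p0: float = 0.5, sidedness: str = "two"
) -> float:
    """Exact binomial test of directional concordance.

    One-sided: P(X >= n_same); two-sided: twice the smaller tail, capped
    at 1.  Under the no-direction null each overlap probe is concordant
    with probability p0 = 1/2.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= n_same <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_same <= n_total and n_total >= 1")
    upper = float(sps.binom.sf(n_same - 1, n_total, p0))
    if sidedness == "one":
        return upper
    if sidedness == "two":
        lower = float(sps.binom.cdf(n_same, n_total, p0))
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError("sidedness must be 'one' or 'two'")


# ----------------------------------------------------------------------
@dataclass
class EnrichmentResult:
    """Overlap table, Monte-Carlo null, hypergeometric p, and
    directional concordance of signature vs dex regulation."""

    table: OverlapTable
    m: int
    exceedances: int
    p_perm: float
    mean_null_overlap: float
    p_hyper: float
    n_same: int
    n_mismatch: int
    p_binom: float
    sidedness: str
    seed: int
    comparison: str = "greater"
    null_overlaps: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        t = self.table
        return "\n".join(
            [
                "Dex-regulation enrichment of the response signature",
                "=" * 55,
                f"common content N = {t.N}, dex-regulated K = {t.K}, signature n = {t.n}",
                f"observed overlap k = {t.k}   (2x2 cells: {t.cells})",
                f"random sets:        m = {self.m}, mean null overlap = {self.mean_null_overlap:.1f}",
                f"sets with overlap {'>' if self.comparison == 'greater' else '>='} {t.k}: {self.exceedances}",
                f"p_perm:             {self.p_perm:.3g}",
                f"p_hypergeometric:   {self.p_hyper:.3g}",
                f"concordance:        {self.n_same} same / {self.n_mismatch} opposite",
                f"p_binomial ({self.sidedness}-sided): {self.p_binom:.3g}",
            ]
        )

    def to_dict(self) -> dict:
        t = self.table
        return {
            "N": t.N, "K": t.K, "n": t.n, "k": t.k,
            "cells": list(t.cells),
            "m": self.m,
            "exceedances": self.exceedances,
            "p_perm": self.p_perm,
            "mean_null_overlap": self.mean_null_overlap,
            "p_hyper": self.p_hyper,
            "n_same": self.n_same,
            "n_mismatch": self.n_mismatch,
            "p_binom": self.p_binom,
            "sidedness": self.sidedness,
            "comparison": self.comparison,
            "seed": self.seed,
        }


class DexEnrichment:
    """Model object: signature (with signs) vs dex regulation (with
    signs) over a common-content universe; ``fit()`` runs all three
    tests and returns an :class:`EnrichmentResult`."""

    def __init__(
        self,
        signature_signs: Mapping[str, int],
        dex_signs: Mapping[str, int],
        universe,
        sidedness: str = "two",
    ) -> None:
        self.universe = sorted(map(str, universe))
        uni = set(self.universe)
        self.signature_signs = {str(p): int(s) for p, s in signature_signs.items() if str(p) in uni}
        self.dex_signs = {str(p): int(s) for p, s in dex_signs.items() if str(p) in uni}
        self.sidedness = sidedness

    def fit(self, m: int = 100_000, seed: int = 0, comparison: str = "greater") -> EnrichmentResult:
        sig = set(self.signature_signs)
        dex = set(self.dex_signs)
        table = overlap_table(sig, dex, self.universe)
        perm = permutation_enrichment(
            table.n, dex, self.universe, table.k, m=m, seed=seed, comparison=comparison
        )
        overlap = sorted(sig & dex)
        n_same, n_mismatch = direction_concordance(self.signature_signs, self.dex_signs, overlap)
        p_binom = binomial_direction_test(
            n_same, max(1, n_same + n_mismatch), sidedness=self.sidedness
        )
        return EnrichmentResult(
            table=table,
            m=perm["m"],
            exceedances=perm["exceedances"],
            p_perm=perm["p_perm"],
            mean_null_overlap=perm["mean_null_overlap"],
            p_hyper=hypergeometric_pvalue(table),
            n_same=n_same,
            n_mismatch=n_mismatch,
            p_binom=p_binom,
            sidedness=self.sidedness,
            seed=seed,
            comparison=comparison,
            null_overlaps=perm["null_overlaps"],
        )
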