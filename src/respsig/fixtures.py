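"""Synthetic reference fixtures with the cardinality structure of the
emulated study.

These are *constructed* (not sampled) objects whose set sizes mirror the
published margins — a 259-probe discovery signature translating to 241
human orthologue genes and 288 array probes (85 / 77 / 66 / 92 for the
stringent q < 0.05 subset), and a 2,852-probe common content with 1,882
dexamethasone-regulated probes overlapping the 179 in-content signature
probes in 134, of which 96 agree in direction.  They exist so the
translation and enrichment machinery can be exercised and verified
against exact expected counts without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .orthology import OrthologyMap

__all__ = ["OrthologyFixture", "DexFixture", "reference_orthology_fixture", "reference_dex_fixture"]


@dataclass
class OrthologyFixture:
    orthology: OrthologyMap
    signature_q10: list[str]  # 259 mouse probes
    signature_q05: list[str]  # 85 mouse probes, subset of signature_q10
    human_universe: list[str]  # post-QC human probe ids


def reference_orthology_fixture() -> OrthologyFixture:
    """Deterministic orthology map reproducing the translation chains
    259 probes -> 241 human genes -> 288 QC probes and
    85 probes -> 77 human genes -> 66 QC genes -> 92 QC probes."""
    rows: list[tuple[str, str, str, str]] = []
    sig_q05: list[str] = []
    sig_q10: list[str] = []
    human_universe: list[str] = []
    mp = hp = 0

    def new_mouse_probe() -> str:
        nonlocal mp
        mp += 1
        return f"MP{mp:04d}"

    def new_human_probe(qc: bool) -> str:
        nonlocal hp
        hp += 1
        pid = f"HP{hp:04d}"
        if qc:
            human_universe.append(pid)
        return pid

    def add_gene(g: int, n_mouse: int, n_human_qc: int, n_human_fail: int, strict: bool) -> None:
        mouse_probes = [new_mouse_probe() for _ in range(n_mouse)]
        human_probes = [new_human_probe(True) for _ in range(n_human_qc)] + [
            new_human_probe(False) for _ in range(n_human_fail)
        ]
        for m in mouse_probes:
            (sig_q05 if strict else sig_q10).append(m)
            for h in human_probes:
                rows.append((m, f"MG{g:05d}", f"HG{g:05d}", h))

    gene = 0
    # strict-signature genes (85 mouse probes over 77 genes)
    for _ in range(8):  # genes with 2 mouse probes and 2 QC human probes
        gene += 1
        add_gene(gene, 2, 2, 0, strict=True)
    for i in range(69):  # single-probe genes; the first 18 carry 2 QC human probes
        gene += 1
        if i < 18:
            add_gene(gene, 1, 2, 0, strict=True)
        elif i < 58:
            add_gene(gene, 1, 1, 0, strict=True)
        else:  # 11 genes whose human probes all fail QC
            add_gene(gene, 1, 0, 1, strict=True)
    # -> 77 human genes, 66 with QC probes, 8*2 + 18*2 + 40*1 = 92 QC probes

    # remaining discovery-signature genes (174 mouse probes: 164 mapped
    # genes + 5 duplicated probes + 5 unmapped genes)
    for _ in range(5):  # mapped genes with 2 mouse probes
        gene += 1
        add_gene(gene, 2, 1, 0, strict=False)
    for i in range(159):
        gene += 1
        if i < 32:
            add_gene(gene, 1, 2, 0, strict=False)
        else:
            add_gene(gene, 1, 1, 0, strict=False)
    # -> 164 more human genes, 5*1 + 32*2 + 127*1 = 196 more QC probes
    for u in range(5):  # unmapped mouse genes: probes with no orthology rows
        sig_q10.append(new_mouse_probe())

    signature_q10 = sig_q05 + sig_q10
    assert len(sig_q05) == 85 and len(signature_q10) == 259
    # pad the human universe with QC-passing background probes
    for _ in range(200):
        new_human_probe(True)
    table = pd.DataFrame(rows, columns=["mouse_probe", "mouse_gene", "human_gene", "human_probe"])
    return OrthologyFixture(
        orthology=OrthologyMap(table),
        signature_q10=signature_q10,
        signature_q05=sig_q05,
        human_universe=human_universe,
    )


@dataclass
class DexFixture:
    universe: list[str]  # 2,852 common-content probes
    signature_signs: dict[str, int]  # 179 probes with effect signs
    dex_signs: dict[str, int]  # 1,882 regulated probes with signs


def reference_dex_fixture() -> DexFixture:
    """Deterministic common content with margins N = 2,852, K = 1,882,
    n = 179, overlap k = 134 and concordance (96 same, 38 opposite)."""
    universe = [f"CP{i:04d}" for i in range(1, 2853)]
    signature = universe[:179]
    signature_signs = {p: 1 for p in signature}
    dex_signs: dict[str, int] = {}
    for i, p in enumerate(universe[:134]):  # overlap: 96 concordant, 38 not
        dex_signs[p] = 1 if i < 96 else -1
    for i, p in enumerate(universe[179 : 179 + 1748]):  # regulated outside the signature
        dex_signs[p] = 1 if i % 2 == 0 else -1
    return DexFixture(universe=universe, signature_signs=signature_signs, dex_signs=dex_signs)
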