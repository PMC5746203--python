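"""Synthetic cohorts with the statistical structure of an extreme-phenotype
antidepressant-response study.

The generator emulates, on the variance-stabilized scale, the data a
cross-species response-signature analysis consumes:

* a treated mouse cohort stratified into good and poor responders by
  forced-swim-test floating time, with blood expression carrying a planted
  responder-associated effect on a known probe set, additive bead-chip
  (batch) offsets, and an additive drug-plasma-concentration term;
* prefrontal-cortex (brain) expression whose signal overlaps the blood
  signal only on a configurable share of probes, with independent signs;
* a paired human cohort (baseline / week 12) where responders — defined by
  a >= 50 % drop in HDRS-17 — show baseline-to-week-12 shifts on the human
  orthologues of the planted mouse signal;
* a dexamethasone-regulation table with controllable overlap and sign
  concordance with the planted signature; and
* a many-to-many mouse-probe -> human-probe orthology map.

Everything is deterministic given ``SimulationConfig.seed``; per-stage
random streams are derived from the master seed by hashing the stage name
(see :func:`stage_rng`), so single stages can be re-run independently and
reproducibly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix
from .orthology import OrthologyMap

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "stage_rng",
    "simulate_mouse_cohort",
    "simulate_human_cohort",
    "simulate_dex_experiment",
    "simulate_orthology_map",
    "simulate_cohort_bundle",
    "write_bundle",
    "read_bundle",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream.

    The stream is seeded from ``SeedSequence([seed, crc32(stage)])`` so
    that (a) the same master seed always yields the same stream for a
    given stage and (b) streams of different stages are statistically
    independent.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults set to the design
    of the emulated experiments (group sizes, class imbalance, overlap
    margins) at a working probe-universe scale.

    Effects are expressed as standardized mean differences in units of the
    residual standard deviation ``noise_sd`` on the transformed scale.
    """

    seed: int = 0
    # universes (post-QC working scale)
    n_probes_mouse: int = 5000
    n_probes_human: int = 6000
    # mouse design: 20 % extremes of a treated arm, plus vehicle controls;
    # the treated arm is n_good + n_poor + n_intermediate animals, sized so
    # the 20 %-extremes rule recovers exactly the good and poor groups
    n_good: int = 12
    n_poor: int = 12
    n_intermediate: int = 36
    n_vehicle: int = 12
    # human cohort: 86 patients, ~63 responders / 23 nonresponders
    n_patients: int = 86
    responder_fraction: float = 63 / 86
    # planted signal
    n_signal_probes: int = 259
    effect_blood: float = 2.0
    effect_human: float = 1.5
    brain_signal_share: float = 0.10
    # technical structure
    n_chips: int = 5
    chip_sd: float = 0.2
    conc_slope: float = 0.005
    conc_missing: int = 4
    brain_plasma_r: float = 0.94
    det_fail_fraction: float = 0.05
    # dexamethasone regulation structure (margins of the 2,852-probe
    # common content with 1,882 regulated probes, 134/179 overlap and
    # 96/134 sign concordance)
    dex_fraction: float = 1882 / 2852
    dex_overlap_boost: float = 0.09
    dex_concordance: float = 96 / 134
    # orthology shape
    probes_per_gene_mouse: float = 1.07
    probes_per_gene_human: float = 1.2
    mapping_rate: float = 0.93
    # residual noise on the transformed scale
    noise_sd: float = 0.5
    # floating-time ranges: default non-overlapping so extreme-group
    # labels are unambiguous; mixed mode exercises tie/overlap handling
    mixed_floating: bool = False

    def validate(self) -> list[str]:
        """Return a list of constraint violations (empty iff valid)."""
        v: list[str] = []
        counts = {
            "n_probes_mouse": self.n_probes_mouse,
            "n_probes_human": self.n_probes_human,
            "n_good": self.n_good,
            "n_poor": self.n_poor,
            "n_intermediate": self.n_intermediate,
            "n_vehicle": self.n_vehicle,
            "n_patients": self.n_patients,
            "n_signal_probes": self.n_signal_probes,
            "n_chips": self.n_chips,
            "conc_missing": self.conc_missing,
        }
        for name, val in counts.items():
            if val < 0:
                v.append(f"{name} must be >= 0 (got {val})")
        if self.n_signal_probes > self.n_probes_mouse:
            v.append("n_signal_probes exceeds n_probes_mouse")
        for name in (
            "responder_fraction",
            "brain_signal_share",
            "dex_fraction",
            "dex_concordance",
            "mapping_rate",
            "det_fail_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                v.append(f"{name} must lie in [0, 1] (got {val})")
        if self.n_chips < 1:
            v.append("n_chips must be >= 1")
        if self.noise_sd <= 0:
            v.append("noise_sd must be > 0")
        if self.chip_sd < 0:
            v.append("chip_sd must be >= 0")
        if self.probes_per_gene_human < 1:
            v.append("probes_per_gene_human must be >= 1")
        if self.probes_per_gene_mouse < 1:
            v.append("probes_per_gene_mouse must be >= 1")
        if not -1.0 <= self.brain_plasma_r <= 1.0:
            v.append("brain_plasma_r must lie in [-1, 1]")
        return v

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


@dataclass
class CohortBundle:
    """Everything one simulated study produces, plus the planted truth."""

    mouse_blood: ExpressionMatrix
    mouse_brain: ExpressionMatrix
    mouse_annotation: pd.DataFrame
    human_baseline: ExpressionMatrix
    human_week12: ExpressionMatrix
    patient_annotation: pd.DataFrame
    orthology: OrthologyMap
    dex_table: pd.DataFrame
    truth: dict
    config: SimulationConfig

    def __post_init__(self) -> None:
        if list(self.mouse_blood.sample_ids) != list(self.mouse_annotation["animal_id"]):
            raise ValueError("mouse blood samples and annotation disagree")
        if list(self.human_baseline.sample_ids) != list(
            self.patient_annotation["patient_id"]
        ):
            raise ValueError("human samples and annotation disagree")
        if not self.human_baseline.probe_ids.equals(self.human_week12.probe_ids):
            raise ValueError("baseline and week-12 probe universes differ")
        if list(self.human_baseline.sample_ids) != list(self.human_week12.sample_ids):
            raise ValueError("baseline and week-12 patient ids differ")


# ----------------------------------------------------------------------
def _mouse_probe_ids(n: int) -> pd.Index:
    return pd.Index([f"mmu_{i:06d}" for i in range(n)], name="probe_id")


def _human_probe_ids(n: int) -> pd.Index:
    return pd.Index([f"hsa_{i:06d}" for i in range(n)], name="probe_id")


def _detection_p(
    rng: np.random.Generator, n_probes: int, n_samples: int, fail: np.ndarray
) -> np.ndarray:
    """Detection p-values: detected probes get Beta(0.5, 10) values
    (overwhelmingly < 0.01); failing probes get Uniform(0.3, 1) and can
    never satisfy a detection rule."""
    detp = rng.beta(0.5, 10.0, size=(n_probes, n_samples))
    detp[fail] = rng.uniform(0.3, 1.0, size=(int(fail.sum()), n_samples))
    return detp


def _correlated_pair(
    rng: np.random.Generator,
    n: int,
    r: float,
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
) -> tuple[np.ndarray, np.ndarray]:
    za = rng.standard_normal(n)
    zb = r * za + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    return mean_a + sd_a * za, mean_b + sd_b * zb


def simulate_mouse_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Simulate blood and brain expression plus animal annotation.

    Blood carries the planted good-vs-poor effect on the first
    ``n_signal_probes`` probes (random sign per probe, magnitude
    ``effect_blood * noise_sd``), additive chip offsets, and an additive
    plasma-concentration term for treated animals.  Brain carries effects
    on only ``brain_signal_share`` of the blood signal probes, with signs
    drawn independently of blood.  Floating times place good animals
    strictly in the lowest and poor animals strictly in the highest range
    of the treated arm (unless ``mixed_floating``).
    """
    config.require_valid()
    if config.n_good == 0 or config.n_poor == 0:
        raise ValueError("contrasted groups must be non-empty (n_good, n_poor >= 1)")
    rng = stage_rng(config.seed, "mouse_cohort")

    n_animals = config.n_good + config.n_poor + config.n_intermediate + config.n_vehicle
    groups = (
        ["good"] * config.n_good
        + ["poor"] * config.n_poor
        + ["intermediate"] * config.n_intermediate
        + ["vehicle"] * config.n_vehicle
    )
    animal_ids = [f"m{i + 1:03d}" for i in range(n_animals)]
    arm = ["paroxetine" if g != "vehicle" else "vehicle" for g in groups]
    treated = np.array([a == "paroxetine" for a in arm])

    # forced-swim-test composition (5-minute test, 300 s budget)
    floating = np.empty(n_animals)
    for i, g in enumerate(groups):
        if config.mixed_floating:
            floating[i] = rng.uniform(40, 240) if g != "vehicle" else rng.uniform(120, 280)
        elif g == "good":
            floating[i] = rng.uniform(40, 90)
        elif g == "poor":
            floating[i] = rng.uniform(180, 240)
        elif g == "intermediate":
            floating[i] = rng.uniform(95, 175)
        else:
            floating[i] = rng.uniform(120, 280)
    rest = 300.0 - floating
    struggle_frac = rng.uniform(0.3, 0.7, n_animals)
    struggling = rest * struggle_frac
    swimming = rest - struggling

    # drug concentrations (ng/mL): brain ~ plasma with correlation r
    plasma = np.zeros(n_animals)
    brain_conc = np.zeros(n_animals)
    n_treated = int(treated.sum())
    p_t, b_t = _correlated_pair(
        rng, n_treated, config.brain_plasma_r, 60.0, 15.0, 400.0, 100.0
    )
    plasma[treated] = np.clip(p_t, 5.0, None)
    brain_conc[treated] = np.clip(b_t, 20.0, None)

    chip_ids = np.array([f"chip{(i % config.n_chips) + 1}" for i in range(n_animals)])
    amp_batches = np.array(
        [f"amp{(i // max(1, -(-n_animals // config.n_chips))) + 1}" for i in range(n_animals)]
    )
    chip_offsets = rng.normal(0.0, config.chip_sd, config.n_chips)
    amp_offsets = rng.normal(0.0, config.chip_sd, config.n_chips)

    probes = _mouse_probe_ids(config.n_probes_mouse)
    base = rng.uniform(6.0, 12.0, config.n_probes_mouse)

    signal_idx = np.arange(config.n_signal_probes)
    blood_signs = rng.choice([-1, 1], size=config.n_signal_probes)

    # blood expression on the transformed scale
    good = np.array([g == "good" for g in groups])
    conc_term = np.zeros(n_animals)
    if n_treated:
        conc_term[treated] = config.conc_slope * (plasma[treated] - plasma[treated].mean())
    chip_term = np.array([chip_offsets[int(c[4:]) - 1] for c in chip_ids])
    blood = (
        base[:, None]
        + chip_term[None, :]
        + conc_term[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_probes_mouse, n_animals))
    )
    blood[np.ix_(signal_idx, np.where(good)[0])] += (
        blood_signs[:, None] * config.effect_blood * config.noise_sd
    )

    # brain expression: independent baseline noise; signal only on a share
    # of the blood signal probes, with signs drawn independently
    n_brain_sig = int(np.floor(config.brain_signal_share * config.n_signal_probes))
    brain_sig_idx = rng.choice(signal_idx, size=n_brain_sig, replace=False) if n_brain_sig else np.array([], dtype=int)
    brain_signs = rng.choice([-1, 1], size=n_brain_sig)
    brain_base = rng.uniform(6.0, 12.0, config.n_probes_mouse)
    amp_term = np.array([amp_offsets[int(a[3:]) - 1] for a in amp_batches])
    brain_conc_term = np.zeros(n_animals)
    if n_treated:
        brain_conc_term[treated] = config.conc_slope * (
            brain_conc[treated] - brain_conc[treated].mean()
        )
    brain = (
        brain_base[:, None]
        + amp_term[None, :]
        + brain_conc_term[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_probes_mouse, n_animals))
    )
    if n_brain_sig:
        brain[np.ix_(brain_sig_idx, np.where(good)[0])] += (
            brain_signs[:, None] * config.effect_blood * config.noise_sd
        )

    # detection p-values; planted probes are kept well detected so the
    # planted truth survives the detection filter
    n_fail = int(round(config.det_fail_fraction * config.n_probes_mouse))
    nonsignal = np.arange(config.n_signal_probes, config.n_probes_mouse)
    fail = np.zeros(config.n_probes_mouse, dtype=bool)
    if n_fail and len(nonsignal):
        fail[rng.choice(nonsignal, size=min(n_fail, len(nonsignal)), replace=False)] = True
    blood_detp = _detection_p(rng, config.n_probes_mouse, n_animals, fail)
    brain_fail = np.zeros(config.n_probes_mouse, dtype=bool)
    if n_fail and len(nonsignal):
        brain_fail[rng.choice(nonsignal, size=min(n_fail, len(nonsignal)), replace=False)] = True
    brain_detp = _detection_p(rng, config.n_probes_mouse, n_animals, brain_fail)

    # blank plasma concentrations for conc_missing treated animals
    missing_plasma: np.ndarray = np.array([], dtype=int)
    if config.conc_missing:
        treated_idx = np.where(treated)[0]
        k = min(config.conc_missing, len(treated_idx))
        missing_plasma = rng.choice(treated_idx, size=k, replace=False)

    annotation = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "arm": arm,
            "floating_s": np.round(floating, 1),
            "struggling_s": np.round(struggling, 1),
            "swimming_s": np.round(swimming, 1),
            "responder": groups,
            "plasma_conc": np.round(plasma, 2),
            "brain_conc": np.round(brain_conc, 2),
            "corticosterone": np.round(rng.lognormal(np.log(120.0), 0.3, n_animals), 1),
            "body_weight_gain": np.round(
                np.where(treated, rng.normal(1.5, 0.5, n_animals), rng.normal(0.8, 0.5, n_animals)),
                2,
            ),
            "chip_id": chip_ids,
            "amp_batch": amp_batches,
        }
    )
    annotation.loc[missing_plasma, "plasma_conc"] = np.nan
    annotation.loc[~treated, "plasma_conc"] = np.nan
    annotation.loc[~treated, "brain_conc"] = np.nan

    samples = pd.Index(animal_ids, name="sample_id")
    blood_mat = ExpressionMatrix(
        pd.DataFrame(blood, index=probes, columns=samples),
        pd.DataFrame(blood_detp, index=probes, columns=samples),
    )
    brain_mat = ExpressionMatrix(
        pd.DataFrame(brain, index=probes, columns=samples),
        pd.DataFrame(brain_detp, index=probes, columns=samples),
    )
    # stash planted truth on the annotation attrs for bundle assembly
    annotation.attrs["truth"] = {
        "signal_probes": {
            str(probes[i]): int(s) for i, s in zip(signal_idx, blood_signs)
        },
        "brain_signal_probes": {
            str(probes[i]): int(s) for i, s in zip(brain_sig_idx, brain_signs)
        },
        "effect_blood": config.effect_blood,
    }
    return blood_mat, brain_mat, annotation


def simulate_human_cohort(
    config: SimulationConfig, signature_human_probes: Iterable[str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Simulate paired baseline / week-12 expression and patient annotation.

    Responder status is Bernoulli(``responder_fraction``); HDRS-17 scores
    are generated so the >= 50 % improvement rule reproduces the drawn
    status.  Responders receive baseline-to-week-12 shifts of magnitude
    ``effect_human * noise_sd`` (random sign per probe, fixed across the
    cohort) on the signature probes; nonresponders receive none.
    """
    config.require_valid()
    rng = stage_rng(config.seed, "human_cohort")
    probes = _human_probe_ids(config.n_probes_human)
    sig = [p for p in signature_human_probes]
    unknown = set(sig) - set(probes)
    if unknown:
        raise ValueError(f"signature probes outside the human universe: {sorted(unknown)[:5]}")

    n = config.n_patients
    responder = rng.random(n) < config.responder_fraction
    if responder.sum() < 2 or (~responder).sum() < 2:
        raise ValueError(
            "responder_fraction leaves fewer than 2 patients in a class; classifier untrainable"
        )
    patient_ids = [f"pt{i + 1:03d}" for i in range(n)]

    baseline_hdrs = rng.integers(18, 31, n).astype(float)
    week12_hdrs = np.empty(n)
    improv_r = rng.uniform(0.55, 0.90, n)
    improv_n = rng.uniform(-0.15, 0.45, n)
    for i in range(n):
        if responder[i]:
            week12_hdrs[i] = np.floor(baseline_hdrs[i] * (1.0 - improv_r[i]))
        else:
            week12_hdrs[i] = np.ceil(baseline_hdrs[i] * (1.0 - improv_n[i]))

    chip_ids = np.array([f"hchip{(i % config.n_chips) + 1}" for i in range(n)])
    chip_offsets = rng.normal(0.0, config.chip_sd, config.n_chips)
    chip_term = np.array([chip_offsets[int(c[5:]) - 1] for c in chip_ids])

    base = rng.uniform(6.0, 12.0, config.n_probes_human)
    baseline = (
        base[:, None]
        + chip_term[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_probes_human, n))
    )
    week12 = (
        base[:, None]
        + chip_term[None, :]
        + rng.normal(0.0, config.noise_sd, (config.n_probes_human, n))
    )
    sig_pos = probes.get_indexer(sig)
    sig_signs = rng.choice([-1, 1], size=len(sig))
    if len(sig):
        week12[np.ix_(sig_pos, np.where(responder)[0])] += (
            sig_signs[:, None] * config.effect_human * config.noise_sd
        )

    n_fail = int(round(config.det_fail_fraction * config.n_probes_human))
    fail = np.zeros(config.n_probes_human, dtype=bool)
    non_sig = np.setdiff1d(np.arange(config.n_probes_human), sig_pos)
    if n_fail and len(non_sig):
        fail[rng.choice(non_sig, size=min(n_fail, len(non_sig)), replace=False)] = True
    detp_base = _detection_p(rng, config.n_probes_human, n, fail)
    detp_week = _detection_p(rng, config.n_probes_human, n, fail)

    annotation = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "hdrs_baseline": baseline_hdrs,
            "hdrs_week12": week12_hdrs,
            "chip_id": chip_ids,
        }
    )
    annotation.attrs["truth"] = {
        "human_signature_probes": {p: int(s) for p, s in zip(sig, sig_signs)},
        "effect_human": config.effect_human,
        "planted_responders": [patient_ids[i] for i in np.where(responder)[0]],
    }
    pts = pd.Index(patient_ids, name="sample_id")
    base_mat = ExpressionMatrix(
        pd.DataFrame(baseline, index=probes, columns=pts),
        pd.DataFrame(detp_base, index=probes, columns=pts),
    )
    week_mat = ExpressionMatrix(
        pd.DataFrame(week12, index=probes, columns=pts),
        pd.DataFrame(detp_week, index=probes, columns=pts),
    )
    return base_mat, week_mat, annotation


def simulate_dex_experiment(
    config: SimulationConfig,
    mouse_universe: Iterable[str],
    signature_signs: Mapping[str, int],
) -> pd.DataFrame:
    """Per-probe dexamethasone-regulation table.

    Non-signature probes are regulated with probability ``dex_fraction``;
    signature probes with ``dex_fraction + dex_overlap_boost`` (capped at
    1 with a warning).  Regulated signature probes share the signature's
    planted sign with probability ``dex_concordance``; other signs are
    random.
    """
    config.require_valid()
    universe = list(mouse_universe)
    missing = set(signature_signs) - set(universe)
    if missing:
        raise ValueError("signature probes outside the mouse universe")
    rng = stage_rng(config.seed, "dex_experiment")
    p_sig = config.dex_fraction + config.dex_overlap_boost
    if p_sig > 1.0:
        import warnings

        warnings.warn(
            "dex_fraction + dex_overlap_boost exceeds 1; capping at 1", stacklevel=2
        )
        p_sig = 1.0

    is_sig = np.array([p in signature_signs for p in universe])
    p_reg = np.where(is_sig, p_sig, config.dex_fraction)
    regulated = rng.random(len(universe)) < p_reg

    signs = np.where(rng.random(len(universe)) < 0.5, 1, -1)
    concordant = rng.random(len(universe)) < config.dex_concordance
    for i, probe in enumerate(universe):
        if is_sig[i] and regulated[i]:
            planted = signature_signs[probe]
            signs[i] = planted if concordant[i] else -planted
    q = np.where(regulated, rng.uniform(0.0, 0.1, len(universe)), rng.uniform(0.1, 1.0, len(universe)))
    return pd.DataFrame(
        {
            "probe_id": universe,
            "regulated": regulated.astype(int),
            "sign": np.where(regulated, signs, 0),
            "q": np.round(q, 6),
        }
    )


def simulate_orthology_map(
    config: SimulationConfig,
    mouse_probes: Iterable[str],
    human_probes: Iterable[str],
) -> OrthologyMap:
    """Random many-to-many orthology with configurable mapping rate and
    human probes-per-gene distribution (1 + Poisson)."""
    config.require_valid()
    mouse_probes = list(mouse_probes)
    human_probes = list(human_probes)
    if not mouse_probes or not human_probes:
        raise ValueError("probe universes must be non-empty")
    rng = stage_rng(config.seed, "orthology")

    # assign mouse probes to genes; a probe lands on an already opened
    # gene with probability 1 - 1/probes_per_gene_mouse, giving that
    # expected number of probes per gene
    p_dup = max(0.0, 1.0 - 1.0 / config.probes_per_gene_mouse)
    gene_of: list[int] = []
    n_genes = 0
    for i in range(len(mouse_probes)):
        if n_genes and rng.random() < p_dup:
            gene_of.append(int(rng.integers(0, n_genes)))
        else:
            gene_of.append(n_genes)
            n_genes += 1

    mapped = rng.random(n_genes) < config.mapping_rate
    extra = max(0.0, config.probes_per_gene_human - 1.0)
    n_hp = 1 + rng.poisson(extra, n_genes)
    order = rng.permutation(len(human_probes))
    rows = []
    cursor = 0
    for g in range(n_genes):
        if not mapped[g]:
            continue
        take = int(n_hp[g])
        if cursor + take > len(human_probes):
            take = len(human_probes) - cursor
            if take <= 0:
                break
        hps = [human_probes[order[cursor + j]] for j in range(take)]
        cursor += take
        mps = [mouse_probes[i] for i, gg in enumerate(gene_of) if gg == g]
        for mp in mps:
            for hp in hps:
                rows.append((mp, f"Mgene{g + 1:05d}", f"Hgene{g + 1:05d}", hp))
    table = pd.DataFrame(rows, columns=["mouse_probe", "mouse_gene", "human_gene", "human_probe"])
    return OrthologyMap(table)


# ----------------------------------------------------------------------
def simulate_cohort_bundle(config: SimulationConfig) -> CohortBundle:
    """Generate the full study: mouse cohort, orthology, human cohort on
    the orthologues of the planted mouse signal, and dex table."""
    config.require_valid()
    blood, brain, mouse_ann = simulate_mouse_cohort(config)
    mouse_truth = mouse_ann.attrs["truth"]
    orthology = simulate_orthology_map(
        config, blood.probe_ids, _human_probe_ids(config.n_probes_human)
    )
    tab = orthology.table
    sig_rows = tab[tab["mouse_probe"].isin(mouse_truth["signal_probes"])]
    sig_human = sorted(sig_rows["human_probe"].unique())
    base_mat, week_mat, patient_ann = simulate_human_cohort(config, sig_human)
    dex = simulate_dex_experiment(config, blood.probe_ids, mouse_truth["signal_probes"])
    truth = {
        **mouse_truth,
        **patient_ann.attrs["truth"],
        "seed": config.seed,
    }
    return CohortBundle(
        mouse_blood=blood,
        mouse_brain=brain,
        mouse_annotation=mouse_ann,
        human_baseline=base_mat,
        human_week12=week_mat,
        patient_annotation=patient_ann,
        orthology=orthology,
        dex_table=dex,
        truth=truth,
        config=config,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a bundle as a directory of TSVs plus truth.json and the
    YAML config used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.mouse_blood.to_tsv(outdir / "mouse_blood.tsv")
    bundle.mouse_brain.to_tsv(outdir / "mouse_brain.tsv")
    bundle.mouse_annotation.to_csv(outdir / "mouse_annotation.tsv", sep="\t", index=False)
    bundle.human_baseline.to_tsv(outdir / "human_baseline.tsv")
    bundle.human_week12.to_tsv(outdir / "human_week12.tsv")
    bundle.patient_annotation.to_csv(outdir / "patient_annotation.tsv", sep="\t", index=False)
    bundle.orthology.to_tsv(outdir / "orthology.tsv")
    bundle.dex_table.to_csv(outdir / "dex_table.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(bundle.config), sort_keys=True))


def read_bundle(indir: str | Path) -> CohortBundle:
    indir = Path(indir)
    config = SimulationConfig(**yaml.safe_load((indir / "config.yaml").read_text()))
    return CohortBundle(
        mouse_blood=ExpressionMatrix.read_tsv(indir / "mouse_blood.tsv"),
        mouse_brain=ExpressionMatrix.read_tsv(indir / "mouse_brain.tsv"),
        mouse_annotation=pd.read_csv(indir / "mouse_annotation.tsv", sep="\t"),
        human_baseline=ExpressionMatrix.read_tsv(indir / "human_baseline.tsv"),
        human_week12=ExpressionMatrix.read_tsv(indir / "human_week12.tsv"),
        patient_annotation=pd.read_csv(indir / "patient_annotation.tsv", sep="\t"),
        orthology=OrthologyMap.read_tsv(indir / "orthology.tsv"),
        dex_table=pd.read_csv(indir / "dex_table.tsv", sep="\t"),
        truth=json.loads((indir / "truth.json").read_text()),
        config=config,
    )
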