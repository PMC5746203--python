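"""End-to-end orchestration: simulate (or load) -> preprocess -> stratify
-> differential expression -> orthologue translation -> classification ->
dexamethasone enrichment, reproducibly from one configuration.

A single ``master_seed`` spawns per-stage seeds deterministically (stage
name hashed into the seed sequence), so the whole run — including every
permutation draw — is byte-reproducible, and individual stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    ClassifierParams,
    SignatureTransferClassifier,
    map_signature_to_human,
)
from .diffexpr import DesignSpec, ProbewiseDE, cross_tissue_pattern
from .enrichment import DexEnrichment
from .matrix import ExpressionMatrix
from .phenotype import impute_plasma_from_brain, label_response, stratify_extremes
from .preprocess import (
    HUMAN_DETECTION_RULE,
    MOUSE_DETECTION_RULE,
    DetectionRule,
    detection_filter,
    variance_filter,
    vst_transform,
)
from .simulate import CohortBundle, SimulationConfig, read_bundle, simulate_cohort_bundle

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "validate_config", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    """A stage failure, carrying the failing stage's name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full-run configuration; defaults follow the emulated analysis
    (detection rules, 5 % variance slider, q thresholds 0.1 / 0.05, 20 %
    extremes, 50 % HDRS response, RBF SVM gamma 0.001 / cost 10, 10,000
    label permutations, 1,000 random panels, 100,000 random sets)."""

    master_seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    data_dir: str | None = None
    apply_vst: bool = False  # simulated data are already on the transformed scale
    mouse_detection: DetectionRule = MOUSE_DETECTION_RULE
    human_detection: DetectionRule = HUMAN_DETECTION_RULE
    variance_threshold: float = 0.05
    q_thresholds: tuple[float, float] = (0.1, 0.05)
    extremes_fraction: float = 0.20
    response_threshold: float = 50.0
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    m_label: int = 10_000
    k_random: int = 1_000
    m_enrich: int = 100_000
    delta_mode: str = "absolute"
    sidedness: str = "two"
    outdir: str | None = None

    def to_dict(self) -> dict:
        # round-trip through JSON so tuples become lists and the result
        # is safe for YAML/JSON serialization
        return json.loads(json.dumps(dataclasses.asdict(self), default=_json_default))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return all constraint violations (empty iff the config is runnable)."""
    v: list[str] = []
    if config.simulation is None and config.data_dir is None:
        v.append("either a simulation block or data_dir must be given")
    if config.simulation is not None:
        v.extend(f"simulation.{msg}" for msg in config.simulation.validate())
    if not 0.0 <= config.variance_threshold <= 1.0:
        v.append("variance_threshold must lie in [0, 1]")
    if not 0.0 < config.extremes_fraction < 0.5:
        v.append("extremes_fraction must lie in (0, 0.5)")
    for q in config.q_thresholds:
        if not 0.0 < q <= 1.0:
            v.append(f"q threshold {q} must lie in (0, 1]")
    if config.response_threshold <= 0:
        v.append("response_threshold must be > 0")
    try:
        ClassifierParams(config.classifier.gamma, config.classifier.cost, config.classifier.scale_features)
    except ValueError as exc:
        v.append(f"classifier: {exc}")
    for name in ("m_label", "k_random", "m_enrich"):
        if getattr(config, name) < 1:
            v.append(f"{name} must be >= 1")
    if config.delta_mode not in ("absolute", "signed"):
        v.append("delta_mode must be 'absolute' or 'signed'")
    if config.sidedness not in ("one", "two"):
        v.append("sidedness must be 'one' or 'two'")
    return v


@dataclass
class RunReport:
    """Per-stage cardinalities plus the classification and enrichment
    results of a pipeline run; serializes deterministically."""

    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2,
            sort_keys=True,
            default=_json_default,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in fixed order and return the RunReport.

    Artifacts (probe statistics, signatures, result JSONs, the report)
    are written to ``config.outdir`` when set.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid PipelineConfig: " + "; ".join(problems))
    report = RunReport(config=config.to_dict(), version=__version__)
    master = config.master_seed

    # ---- stage: data -------------------------------------------------
    @_stage("simulate")
    def _get_bundle() -> CohortBundle:
        if config.data_dir is not None:
            return read_bundle(config.data_dir)
        sim = dataclasses.replace(config.simulation, seed=stage_seed(master, "simulate"))
        return simulate_cohort_bundle(sim)

    bundle = _get_bundle()
    report.stages["simulate"] = {
        "seed": bundle.config.seed,
        "n_probes_mouse": bundle.mouse_blood.n_probes,
        "n_probes_human": bundle.human_baseline.n_probes,
        "n_animals": len(bundle.mouse_annotation),
        "n_patients": len(bundle.patient_annotation),
    }

    # ---- stage: preprocess (mouse blood/brain) -----------------------
    @_stage("preprocess")
    def _preprocess():
        blood = detection_filter(bundle.mouse_blood, config.mouse_detection)
        brain = detection_filter(bundle.mouse_brain, config.mouse_detection)
        if config.apply_vst:
            blood, brain = vst_transform(blood), vst_transform(brain)
        return blood, brain

    blood, brain = _preprocess()
    report.stages["preprocess"] = {
        "blood_probes_in": bundle.mouse_blood.n_probes,
        "blood_probes_detected": blood.n_probes,
        "blood_probes_dropped": bundle.mouse_blood.n_probes - blood.n_probes,
        "brain_probes_detected": brain.n_probes,
    }

    # ---- stage: stratify / covariates --------------------------------
    @_stage("stratify")
    def _stratify():
        ann = stratify_extremes(bundle.mouse_annotation, config.extremes_fraction)
        # concentrations exist only in the treated arm; impute there
        treated = ann[ann["arm"] == "paroxetine"]
        imputed = impute_plasma_from_brain(treated)
        ann = pd.concat([imputed, ann[ann["arm"] != "paroxetine"]]).loc[ann.index]
        ann.attrs["plasma_imputation"] = imputed.attrs.get("plasma_imputation", {})
        return ann

    mouse_ann = _stratify()
    counts = mouse_ann["responder"].value_counts().to_dict()
    report.stages["stratify"] = {
        "n_good": int(counts.get("good", 0)),
        "n_poor": int(counts.get("poor", 0)),
        "n_intermediate": int(counts.get("intermediate", 0)),
        "n_vehicle": int(counts.get("vehicle", 0)),
        "plasma_imputation": mouse_ann.attrs.get("plasma_imputation", {}),
    }

    # ---- stage: differential expression ------------------------------
    @_stage("diffexpr")
    def _de():
        gp = mouse_ann[mouse_ann["responder"].isin(["good", "poor"])]
        blood_gp = variance_filter(
            blood.subset_samples(gp["animal_id"]), config.variance_threshold
        )
        de_blood = ProbewiseDE(
            blood_gp,
            gp,
            DesignSpec(
                group="responder",
                levels=("poor", "good"),
                categorical_covariates=("chip_id",),
                continuous_covariates=("plasma_conc",),
            ),
        ).fit()
        brain_gp = variance_filter(
            brain.subset_samples(gp["animal_id"]), config.variance_threshold
        )
        de_brain = ProbewiseDE(
            brain_gp,
            gp,
            DesignSpec(
                group="responder",
                levels=("poor", "good"),
                categorical_covariates=("amp_batch",),
                continuous_covariates=("brain_conc",),
            ),
        ).fit()
        # treatment-vs-vehicle contrast on its own variance-filter universe
        tv = mouse_ann.copy()
        blood_tv = variance_filter(blood, config.variance_threshold)
        de_treat = ProbewiseDE(
            blood_tv,
            tv,
            DesignSpec(group="arm", levels=("vehicle", "paroxetine"),
                       categorical_covariates=("chip_id",)),
        ).fit()
        return de_blood, de_brain, de_treat

    de_blood, de_brain, de_treat = _de()
    q_loose, q_strict = sorted(config.q_thresholds, reverse=True)
    sig_loose = de_blood.select_signature(q_loose)
    sig_strict = de_blood.select_signature(q_strict)
    report.stages["diffexpr"] = {
        "blood_probes_tested": len(de_blood.stats),
        "brain_probes_tested": len(de_brain.stats),
        "treatment_probes_tested": len(de_treat.stats),
        f"signature_q{q_loose:g}": len(sig_loose),
        f"signature_q{q_strict:g}": len(sig_strict),
        f"treatment_hits_q{q_loose:g}": int((de_treat.stats["q"] < q_loose).sum()),
    }

    # ---- stage: cross-tissue pattern ---------------------------------
    @_stage("cross_tissue")
    def _cross():
        return cross_tissue_pattern(de_blood.stats, de_brain.stats, sig_loose["probe_id"])

    if len(sig_loose) >= 2:
        ct = _cross()
        report.stages["cross_tissue"] = {
            "probes_compared": len(ct.table),
            "blood_brain_correlation": ct.correlation,
        }
    else:
        ct = None
        report.stages["cross_tissue"] = {"probes_compared": 0, "blood_brain_correlation": None}

    # ---- stage: translate --------------------------------------------
    @_stage("translate")
    def _translate():
        hb = detection_filter(bundle.human_baseline, config.human_detection)
        hw = detection_filter(bundle.human_week12, config.human_detection)
        universe = sorted(set(hb.probe_ids) & set(hw.probe_ids))
        hb, hw = hb.subset_probes(universe), hw.subset_probes(universe)
        mappings = {}
        for name, sig in (("loose", sig_loose), ("strict", sig_strict)):
            if len(sig):
                try:
                    mappings[name] = map_signature_to_human(
                        sig["probe_id"], bundle.orthology, universe
                    )
                except ValueError:
                    mappings[name] = None
            else:
                mappings[name] = None
        return hb, hw, universe, mappings

    hb, hw, human_universe, mappings = _translate()
    report.stages["translate"] = {
        "human_probes_qc": len(human_universe),
        **{
            f"{name}_{attr}": (getattr(mp, attr) if mp else 0)
            for name, mp in mappings.items()
            for attr in (
                "n_mouse_probes",
                "n_human_genes",
                "n_human_genes_qc",
                "n_human_probes",
            )
        },
    }

    # ---- stage: classify ---------------------------------------------
    @_stage("classify")
    def _classify():
        pats = label_response(bundle.patient_annotation, config.response_threshold)
        labels = pd.Series(
            pats["responder"].to_numpy(), index=pats["patient_id"], name="responder"
        )
        results = {}
        for name, mp in mappings.items():
            if mp is None:
                results[name] = None
                continue
            model = SignatureTransferClassifier(
                hb, hw, labels, mp.human_probes, config.classifier, mode=config.delta_mode
            )
            label_res, feat_res = model.fit(
                seed=stage_seed(master, f"classify_{name}"),
                m_label=config.m_label,
                k_random=config.k_random,
                universe=human_universe,
            )
            results[name] = (label_res, feat_res)
        return pats, results

    patient_ann, clf_results = _classify()
    n_resp = int(patient_ann["responder"].sum())
    report.stages["classify"] = {
        "n_responders": n_resp,
        "n_nonresponders": len(patient_ann) - n_resp,
        **{
            f"{name}_{res.kind}": res.to_dict()
            for name, pair in clf_results.items()
            if pair is not None
            for res in pair
        },
    }

    # ---- stage: enrich -----------------------------------------------
    @_stage("enrich")
    def _enrich():
        dex = bundle.dex_table
        common = sorted(set(blood.probe_ids) & set(dex["probe_id"].astype(str)))
        sig_in = sig_loose[sig_loose["probe_id"].isin(common)]
        if len(sig_in) == 0:
            return None, len(common)
        sig_signs = dict(zip(sig_in["probe_id"], sig_in["sign"]))
        reg = dex[dex["regulated"].astype(bool)]
        dex_signs = {
            str(p): int(s)
            for p, s in zip(reg["probe_id"], reg["sign"])
            if str(p) in set(common)
        }
        model = DexEnrichment(sig_signs, dex_signs, common, sidedness=config.sidedness)
        return (
            model.fit(m=config.m_enrich, seed=stage_seed(master, "enrich")),
            len(common),
        )

    enrich_res, n_common = _enrich()
    report.stages["enrich"] = (
        {"common_content": n_common, **enrich_res.to_dict()}
        if enrich_res is not None
        else {"common_content": n_common, "note": "no signature probes in common content"}
    )

    # ---- artifacts ----------------------------------------------------
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        de_blood.to_tsv(outdir / "de_blood.tsv")
        de_brain.to_tsv(outdir / "de_brain.tsv")
        de_treat.to_tsv(outdir / "de_treatment.tsv")
        sig_loose.to_csv(outdir / f"signature_q{q_loose:g}.tsv", sep="\t", index=False)
        sig_strict.to_csv(outdir / f"signature_q{q_strict:g}.tsv", sep="\t", index=False)
        de_blood.volcano_table().to_csv(outdir / "volcano_blood.tsv", sep="\t", index=False)
        if ct is not None:
            ct.ordered().to_csv(outdir / "cross_tissue.tsv", sep="\t", index=False)
        report.write(outdir / "run_report.json")
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return report
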