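"""Cross-species signature transfer and permutation-validated classification.

A mouse probe signature is mapped through orthologue genes onto human
array probes; per-patient features are the (absolute) baseline-to-week-12
expression differences on those probes.  A soft-margin support vector
machine with a radial-basis-function kernel (gamma = 0.001, cost = 10 —
the defaults of the analysis this emulates) is trained on half of the
patients and evaluated on the other half, and the observed test accuracy
is referred to two permutation nulls:

* label permutation — training labels shuffled m times, classifier refit;
* random feature sets — size-matched probe panels drawn uniformly from
  the post-QC universe, features rebuilt, classifier retrained.

Permutation p-values use the add-one rule ``(b + 1) / (m + 1)`` with the
"equal or better" exceedance convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .matrix import ExpressionMatrix
from .orthology import OrthologyMap

__all__ = [
    "ClassifierParams",
    "ClassificationResult",
    "MappingResult",
    "SignatureTransferClassifier",
    "map_signature_to_human",
    "delta_features",
    "split_train_test",
    "train_classifier",
    "predict",
    "accuracy",
    "permutation_pvalue",
    "label_permutation_test",
    "random_feature_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierParams:
    """Soft-margin RBF support vector machine settings."""

    gamma: float = 0.001
    cost: float = 10.0
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")


@dataclass
class MappingResult:
    """Cardinality chain of a mouse -> human signature translation."""

    human_probes: list[str]
    n_mouse_probes: int
    n_mouse_probes_mapped: int
    n_mouse_genes: int
    n_human_genes: int
    n_human_genes_qc: int

    @property
    def n_human_probes(self) -> int:
        return len(self.human_probes)


def map_signature_to_human(
    signature, orthology: OrthologyMap, human_universe
) -> MappingResult:
    """Translate mouse signature probes to post-QC human probes.

    mouse probes -> mouse genes -> human orthologue genes -> all human
    probes of those genes that survive human QC.  Unmapped mouse probes
    are dropped (and counted); an empty final probe set is an error.
    """
    sig = set(map(str, signature))
    universe = set(map(str, human_universe))
    tab = orthology.table
    rows = tab[tab["mouse_probe"].isin(sig)]
    mapped_probes = set(rows["mouse_probe"])
    n_unmapped = len(sig) - len(mapped_probes)
    if n_unmapped:
        logger.info("map_signature_to_human: %d mouse probes had no orthologue rows", n_unmapped)
    qc_rows = rows[rows["human_probe"].isin(universe)]
    human_probes = sorted(set(qc_rows["human_probe"]))
    if not human_probes:
        raise ValueError("signature maps to no QC-passing human probes; nothing to classify")
    result = MappingResult(
        human_probes=human_probes,
        n_mouse_probes=len(sig),
        n_mouse_probes_mapped=len(mapped_probes),
        n_mouse_genes=rows["mouse_gene"].nunique(),
        n_human_genes=rows["human_gene"].nunique(),
        n_human_genes_qc=qc_rows["human_gene"].nunique(),
    )
    logger.info(
        "map_signature_to_human: %d probes -> %d human genes -> %d QC genes -> %d human probes",
        result.n_mouse_probes, result.n_human_genes, result.n_human_genes_qc,
        result.n_human_probes,
    )
    return result


def delta_features(
    baseline: ExpressionMatrix,
    week12: ExpressionMatrix,
    probes,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Patients x probes matrix of baseline-to-week-12 expression change.

    ``absolute`` (default) takes |week12 - baseline|; ``signed`` keeps the
    difference.  Patient order follows the baseline matrix.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    probes = [str(p) for p in probes]
    for name, mat in (("baseline", baseline), ("week12", week12)):
        missing = [p for p in probes if p not in mat.probe_ids]
        if missing:
            raise ValueError(f"probes absent from {name} matrix: {missing[:5]}")
    if list(baseline.sample_ids) != list(week12.sample_ids):
        raise ValueError("baseline and week12 patients differ")
    diff = (
        week12.values.loc[probes].to_numpy() - baseline.values.loc[probes].to_numpy()
    ).T  # patients x probes
    if mode == "absolute":
        diff = np.abs(diff)
    return pd.DataFrame(diff, index=baseline.sample_ids, columns=probes)


def split_train_test(
    patients, labels, seed: int, stratified: bool = True
) -> tuple[list, list]:
    """Deterministic half split; with stratification each class's
    proportions in the halves differ by at most one patient.  On odd n
    the training half receives the extra patient."""
    patients = list(patients)
    labels = np.asarray(list(labels))
    if len(patients) != len(labels):
        raise ValueError("patients and labels length mismatch")
    n = len(patients)
    n_train = (n + 1) // 2
    rng = np.random.default_rng(seed)
    if not stratified:
        order = rng.permutation(n)
        train = [patients[i] for i in order[:n_train]]
        test = [patients[i] for i in order[n_train:]]
    else:
        classes = sorted(set(labels.tolist()), key=str)
        take = {}
        remainders = []
        total = 0
        for c in classes:
            n_c = int((labels == c).sum())
            take[c] = n_c // 2
            total += n_c // 2
            remainders.append((c, n_c % 2))
        short = n_train - total
        extras = [c for c, r in remainders if r]
        rng.shuffle(extras)
        for c in extras[:short]:
            take[c] += 1
        train, test = [], []
        for c in classes:
            idx = np.where(labels == c)[0]
            rng.shuffle(idx)
            train.extend(patients[i] for i in idx[: take[c]])
            test.extend(patients[i] for i in idx[take[c]:])
    for half, name in ((train, "training"), (test, "test")):
        got = {labels[patients.index(p)] for p in half}
        if len(got) < len(set(labels.tolist())):
            raise ValueError(f"a class is absent from the {name} half")
    return train, test


# ----------------------------------------------------------------------
@dataclass
class _FittedSVM:
    svc: SVC
    mean: np.ndarray | None
    sd: np.ndarray | None
    kept: np.ndarray  # boolean mask over feature columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = X[:, self.kept]
        if self.mean is not None:
            X = (X - self.mean) / self.sd
        return X


def train_classifier(features, labels, params: ClassifierParams) -> _FittedSVM:
    """Fit the soft-margin RBF SVM; features are standardized with
    training-set statistics when ``params.scale_features``.  Zero-variance
    features cannot be standardized and are dropped with a warning."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    kept = np.ones(X.shape[1], dtype=bool)
    mean = sd = None
    if params.scale_features:
        sd_all = X.std(axis=0, ddof=0)
        kept = sd_all > 0
        if not kept.all():
            warnings.warn(
                f"dropping {int((~kept).sum())} zero-variance feature(s) before scaling",
                stacklevel=2,
            )
        if not kept.any():
            raise ValueError("all features have zero variance")
        mean = X[:, kept].mean(axis=0)
        sd = sd_all[kept]
    svc = SVC(kernel="rbf", gamma=params.gamma, C=params.cost)
    fitted = _FittedSVM(svc=svc, mean=mean, sd=sd, kept=kept)
    svc.fit(fitted.transform(X), y)
    return fitted


def predict(model: _FittedSVM, features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    return model.svc.predict(model.transform(X))


def accuracy(predicted, truth) -> float:
    predicted = np.asarray(list(predicted))
    truth = np.asarray(list(truth))
    if predicted.size != truth.size or predicted.size == 0:
        raise ValueError("predicted and truth must have equal nonzero length")
    return float((predicted == truth).mean())


def permutation_pvalue(observed: float, nulls, orientation: str = "greater_equal") -> float:
    """Add-one permutation p-value: (#{null >= observed} + 1) / (m + 1)."""
    nulls = np.asarray(list(nulls), dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if orientation == "greater_equal":
        b = int((nulls >= observed).sum())
    elif orientation == "greater":
        b = int((nulls > observed).sum())
    else:
        raise ValueError("orientation must be 'greater_equal' or 'greater'")
    return (b + 1) / (nulls.size + 1)


@dataclass
class ClassificationResult:
    """Observed test accuracy against a permutation null."""

    accuracy: float
    n_test: int
    null_accuracies: np.ndarray
    exceedances: int
    p_perm: float
    seed: int
    m: int
    kind: str = "label_permutation"

    def summary(self) -> str:
        nulls = self.null_accuracies
        return "\n".join(
            [
                f"Signature classification ({self.kind})",
                "=" * 50,
                f"test accuracy:     {self.accuracy:.4f}  (n_test = {self.n_test})",
                f"null models:       {self.m}",
                f"null median:       {np.median(nulls):.4f}",
                f"nulls >= observed: {self.exceedances}",
                f"p_perm:            {self.p_perm:.4g}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "m": self.m,
            "exceedances": self.exceedances,
            "p_perm": self.p_perm,
            "null_median": float(np.median(self.null_accuracies)),
            "seed": self.seed,
        }


def _fit_eval(Xtr, ytr, Xte, yte, params) -> float:
    model = train_classifier(Xtr, ytr, params)
    return accuracy(predict(model, Xte), yte)


def label_permutation_test(
    train_ids,
    test_ids,
    features: pd.DataFrame,
    labels: pd.Series,
    params: ClassifierParams,
    m: int = 10_000,
    seed: int = 0,
) -> ClassificationResult:
    """Observed accuracy vs the null of m training-label shuffles.

    Each permutation shuffles the training labels, refits the classifier
    from scratch, and records test accuracy.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    Xtr = features.loc[train_ids].to_numpy(dtype=float)
    Xte = features.loc[test_ids].to_numpy(dtype=float)
    ytr = labels.loc[train_ids].to_numpy()
    yte = labels.loc[test_ids].to_numpy()
    observed = _fit_eval(Xtr, ytr, Xte, yte, params)
    rng = np.random.default_rng(seed)
    nulls = np.empty(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance warning repeats per refit
        for i in range(m):
            nulls[i] = _fit_eval(Xtr, rng.permutation(ytr), Xte, yte, params)
    exceed = int((nulls >= observed).sum())
    return ClassificationResult(
        accuracy=observed,
        n_test=len(yte),
        null_accuracies=nulls,
        exceedances=exceed,
        p_perm=permutation_pvalue(observed, nulls),
        seed=seed,
        m=m,
        kind="label_permutation",
    )


def random_feature_test(
    baseline: ExpressionMatrix,
    week12: ExpressionMatrix,
    labels: pd.Series,
    selected_panel,
    universe,
    train_ids,
    test_ids,
    params: ClassifierParams,
    k: int = 1_000,
    seed: int = 0,
    mode: str = "absolute",
) -> ClassificationResult:
    """Observed accuracy vs k size-matched random probe panels.

    Each null panel is drawn uniformly without replacement from the
    post-QC universe; its delta features are rebuilt and the classifier
    retrained and tested on the same patient split.
    """
    panel = [str(p) for p in selected_panel]
    universe = sorted(map(str, universe))
    if len(panel) > len(universe):
        raise ValueError("selected panel larger than the sampling universe")
    feats = delta_features(baseline, week12, panel, mode=mode)
    Xtr, Xte = feats.loc[train_ids].to_numpy(), feats.loc[test_ids].to_numpy()
    ytr = labels.loc[train_ids].to_numpy()
    yte = labels.loc[test_ids].to_numpy()
    observed = _fit_eval(Xtr, ytr, Xte, yte, params)

    # precompute the full delta matrix once; each draw is a column subset
    all_feats = delta_features(baseline, week12, universe, mode=mode)
    Atr = all_feats.loc[train_ids].to_numpy()
    Ate = all_feats.loc[test_ids].to_numpy()
    rng = np.random.default_rng(seed)
    nulls = np.empty(k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(k):
            cols = rng.choice(len(universe), size=len(panel), replace=False)
            nulls[i] = _fit_eval(Atr[:, cols], ytr, Ate[:, cols], yte, params)
    exceed = int((nulls >= observed).sum())
    return ClassificationResult(
        accuracy=observed,
        n_test=len(yte),
        null_accuracies=nulls,
        exceedances=exceed,
        p_perm=permutation_pvalue(observed, nulls),
        seed=seed,
        m=k,
        kind="random_features",
    )


# ----------------------------------------------------------------------
class SignatureTransferClassifier:
    """Model object tying together paired human expression, response
    labels and a translated probe panel.

    ``fit()`` performs the half-split evaluation plus both permutation
    nulls and returns the two :class:`ClassificationResult` objects.
    """

    def __init__(
        self,
        baseline: ExpressionMatrix,
        week12: ExpressionMatrix,
        labels: pd.Series,
        panel,
        params: ClassifierParams = ClassifierParams(),
        mode: str = "absolute",
    ) -> None:
        self.baseline = baseline
        self.week12 = week12
        self.labels = labels
        self.panel = [str(p) for p in panel]
        self.params = params
        self.mode = mode

    def fit(
        self,
        seed: int = 0,
        m_label: int = 10_000,
        k_random: int = 1_000,
        universe=None,
    ) -> tuple[ClassificationResult, ClassificationResult]:
        feats = delta_features(self.baseline, self.week12, self.panel, mode=self.mode)
        patients = list(feats.index)
        train, test = split_train_test(patients, self.labels.loc[patients], seed=seed)
        label_res = label_permutation_test(
            train, test, feats, self.labels, self.params, m=m_label, seed=seed + 1
        )
        if universe is None:
            universe = list(self.baseline.probe_ids)
        feat_res = random_feature_test(
            self.baseline,
            self.week12,
            self.labels,
            self.panel,
            universe,
            train,
            test,
            self.params,
            k=k_random,
            seed=seed + 2,
            mode=self.mode,
        )
        return label_res, feat_res
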