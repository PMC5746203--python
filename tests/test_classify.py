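"""Orthologue translation, delta features, splitting, the SVM, and the
two permutation nulls."""

import numpy as np
import pandas as pd
import pytest

from respsig.classify import (
    ClassifierParams,
    accuracy,
    delta_features,
    label_permutation_test,
    map_signature_to_human,
    permutation_pvalue,
    predict,
    random_feature_test,
    split_train_test,
    train_classifier,
)
from respsig.fixtures import reference_orthology_fixture
from respsig.matrix import ExpressionMatrix
from respsig.orthology import OrthologyMap


def _emx(values, probes, samples):
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(probes, name="probe_id"),
            columns=pd.Index(samples, name="sample_id"),
        )
    )


class TestSignatureMapping:
    def test_discovery_chain_cardinalities(self):
        fx = reference_orthology_fixture()
        res = map_signature_to_human(fx.signature_q10, fx.orthology, fx.human_universe)
        assert res.n_mouse_probes == 259
        assert res.n_human_genes == 241
        assert res.n_human_probes == 288

    def test_stringent_chain_cardinalities(self):
        fx = reference_orthology_fixture()
        res = map_signature_to_human(fx.signature_q05, fx.orthology, fx.human_universe)
        assert (res.n_mouse_probes, res.n_human_genes) == (85, 77)
        assert (res.n_human_genes_qc, res.n_human_probes) == (66, 92)

    def test_identity_map_roundtrips(self):
        probes = [f"x{i}" for i in range(10)]
        table = pd.DataFrame(
            {
                "mouse_probe": probes,
                "mouse_gene": probes,
                "human_gene": probes,
                "human_probe": probes,
            }
        )
        res = map_signature_to_human(probes[:4], OrthologyMap(table), probes)
        assert res.human_probes == sorted(probes[:4])

    def test_empty_mapping_errors(self):
        fx = reference_orthology_fixture()
        with pytest.raises(ValueError, match="nothing to classify"):
            map_signature_to_human(["absent"], fx.orthology, fx.human_universe)


class TestDeltaFeatures:
    def _pair(self, seed=0, n_probes=5, n_patients=4):
        rng = np.random.default_rng(seed)
        probes = [f"hp{i}" for i in range(n_probes)]
        pats = [f"pt{i}" for i in range(n_patients)]
        a = _emx(rng.normal(8, 1, (n_probes, n_patients)), probes, pats)
        b = _emx(rng.normal(8, 1, (n_probes, n_patients)), probes, pats)
        return a, b, probes

    def test_identical_matrices_zero_features(self):
        a, _, probes = self._pair()
        f = delta_features(a, a, probes)
        assert (f.to_numpy() == 0).all()

    def test_absolute_nonnegative_and_symmetric(self):
        a, b, probes = self._pair(1)
        f1 = delta_features(a, b, probes)
        f2 = delta_features(b, a, probes)
        assert (f1.to_numpy() >= 0).all()
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy())

    def test_signed_mode_antisymmetric(self):
        a, b, probes = self._pair(2)
        f1 = delta_features(a, b, probes, mode="signed")
        f2 = delta_features(b, a, probes, mode="signed")
        np.testing.assert_allclose(f1.to_numpy(), -f2.to_numpy())

    def test_missing_probe_named(self):
        a, b, _ = self._pair()
        with pytest.raises(ValueError, match="ghost"):
            delta_features(a, b, ["ghost"])


class TestSplit:
    def test_86_patients_split_43_43(self):
        pats = [f"pt{i}" for i in range(86)]
        labels = [True] * 63 + [False] * 23
        train, test = split_train_test(pats, labels, seed=0)
        assert len(train) == 43 and len(test) == 43
        lab = dict(zip(pats, labels))
        n_resp_train = sum(lab[p] for p in train)
        assert n_resp_train in (31, 32)

    def test_odd_n_extra_to_train(self):
        train, test = split_train_test(list("abcdefg"), [0, 0, 0, 0, 1, 1, 1], seed=1)
        assert len(train) == 4 and len(test) == 3

    def test_deterministic_given_seed(self):
        pats = [f"pt{i}" for i in range(30)]
        labels = [i % 2 for i in range(30)]
        assert split_train_test(pats, labels, seed=5) == split_train_test(pats, labels, seed=5)
        assert split_train_test(pats, labels, seed=5) != split_train_test(pats, labels, seed=6)

    def test_singleton_class_errors(self):
        with pytest.raises(ValueError, match="absent"):
            split_train_test(list("abcd"), [0, 0, 0, 1], seed=0)


class TestSVM:
    def _clouds(self, n=40, sep=6.0, seed=0, d=5):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, 1, (n // 2, d)), rng.normal(sep / np.sqrt(d), 1, (n // 2, d))]
        )
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_separable_clouds_high_accuracy(self):
        Xtr, ytr = self._clouds(seed=0)
        Xte, yte = self._clouds(seed=1)
        model = train_classifier(Xtr, ytr, ClassifierParams())
        assert accuracy(predict(model, Xte), yte) >= 0.95

    def test_random_labels_near_majority_rate(self):
        rng = np.random.default_rng(2)
        accs = []
        for seed in range(20):
            Xtr, _ = self._clouds(seed=seed)
            ytr = rng.permutation([0] * 20 + [1] * 20)
            Xte, yte = self._clouds(seed=seed + 100)
            model = train_classifier(Xtr, ytr, ClassifierParams())
            accs.append(accuracy(predict(model, Xte), yte))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_duplicating_training_samples_invariant(self):
        Xtr, ytr = self._clouds(seed=3)
        Xte, _ = self._clouds(seed=4)
        m1 = train_classifier(Xtr, ytr, ClassifierParams())
        m2 = train_classifier(np.vstack([Xtr, Xtr]), np.hstack([ytr, ytr]), ClassifierParams())
        np.testing.assert_array_equal(predict(m1, Xte), predict(m2, Xte))

    def test_zero_variance_feature_dropped_with_warning(self):
        Xtr, ytr = self._clouds(seed=5)
        Xtr = np.hstack([Xtr, np.ones((len(Xtr), 1))])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = train_classifier(Xtr, ytr, ClassifierParams())
        assert model.kept.sum() == Xtr.shape[1] - 1

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.zeros(10), ClassifierParams())

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ClassifierParams(gamma=-1)
        with pytest.raises(ValueError):
            ClassifierParams(cost=0)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_printed_accuracy_denominator_43(self):
        # 33 of 43 matches is the only denominator-43 fraction printing 76.74 %
        pred = [1] * 33 + [0] * 10
        assert f"{accuracy(pred, [1] * 43) * 100:.2f}" == "76.74"

    def test_permuted_labels_expected_accuracy_closed_form(self):
        rng = np.random.default_rng(7)
        truth = np.array([1] * 30 + [0] * 12)
        pred = np.array([1] * 25 + [0] * 17)
        expected = (30 / 42) * (25 / 42) + (12 / 42) * (17 / 42)
        sim = np.mean([accuracy(pred, rng.permutation(truth)) for _ in range(3000)])
        assert sim == pytest.approx(expected, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy([1], [1, 0])


class TestPermutationPvalue:
    def test_printed_convention_25_of_1000(self):
        nulls = np.concatenate([np.full(25, 0.9), np.full(975, 0.1)])
        p = permutation_pvalue(0.7674, nulls)
        assert p == pytest.approx(26 / 1001)
        assert round(p, 3) == 0.026

    def test_zero_of_nine(self):
        assert permutation_pvalue(1.0, [0.1] * 9) == pytest.approx(0.1)

    def test_all_exceed_gives_one(self):
        assert permutation_pvalue(0.0, [0.5] * 7) == 1.0

    def test_never_zero(self):
        assert permutation_pvalue(200.0, list(range(100))) == pytest.approx(1 / 101)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(1.0, [])


def _human_fixture(seed=0, n_pat=86, n_probes=300, n_signal=12, effect=0.0):
    rng = np.random.default_rng(seed)
    probes = [f"hp{i}" for i in range(n_probes)]
    pats = [f"pt{i}" for i in range(n_pat)]
    labels = pd.Series(
        np.array([True] * (n_pat // 2) + [False] * (n_pat - n_pat // 2)), index=pats
    )
    base = rng.normal(8, 0.5, (n_probes, n_pat))
    week = rng.normal(8, 0.5, (n_probes, n_pat))
    week[:n_signal, : n_pat // 2] += effect
    return (
        _emx(base, probes, pats),
        _emx(week, probes, pats),
        labels,
        probes,
    )


class TestPermutationTests:
    def test_label_permutation_deterministic_and_powered(self):
        base, week, labels, probes = _human_fixture(seed=0, effect=2.0)
        feats = delta_features(base, week, probes[:20])
        train, test = split_train_test(list(labels.index), labels, seed=0)
        r1 = label_permutation_test(train, test, feats, labels, ClassifierParams(), m=200, seed=3)
        r2 = label_permutation_test(train, test, feats, labels, ClassifierParams(), m=200, seed=3)
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)
        assert r1.p_perm <= 0.05
        assert r1.p_perm == pytest.approx((r1.exceedances + 1) / 201)

    def test_random_feature_test_strong_panel(self):
        base, week, labels, probes = _human_fixture(seed=2, effect=2.0)
        train, test = split_train_test(list(labels.index), labels, seed=0)
        res = random_feature_test(
            base, week, labels, probes[:12], probes, train, test,
            ClassifierParams(), k=200, seed=4,
        )
        assert res.p_perm <= 0.05
        assert res.m == 200

    def test_panel_larger_than_universe_rejected(self):
        base, week, labels, probes = _human_fixture()
        train, test = split_train_test(list(labels.index), labels, seed=0)
        with pytest.raises(ValueError, match="larger"):
            random_feature_test(
                base, week, labels, probes, probes[:5], train, test,
                ClassifierParams(), k=5, seed=0,
            )

    def test_result_summary_and_dict(self):
        base, week, labels, probes = _human_fixture(seed=3, effect=2.0)
        feats = delta_features(base, week, probes[:10])
        train, test = split_train_test(list(labels.index), labels, seed=0)
        res = label_permutation_test(train, test, feats, labels, ClassifierParams(), m=50, seed=1)
        assert "p_perm" in res.summary()
        d = res.to_dict()
        assert d["m"] == 50 and 0 < d["p_perm"] <= 1
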