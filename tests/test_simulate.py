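"""Generator contracts: determinism, planted-truth bookkeeping, marginal
calibration, and the shapes of the four synthetic datasets."""

import numpy as np
import pandas as pd
import pytest

from respsig.classify import map_signature_to_human
from respsig.preprocess import MOUSE_DETECTION_RULE, detection_filter
from respsig.simulate import (
    SimulationConfig,
    simulate_cohort_bundle,
    simulate_dex_experiment,
    simulate_human_cohort,
    simulate_mouse_cohort,
    simulate_orthology_map,
)
from conftest import small_config


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        a = simulate_cohort_bundle(small_config(seed=3))
        b = simulate_cohort_bundle(small_config(seed=3))
        pd.testing.assert_frame_equal(a.mouse_blood.values, b.mouse_blood.values)
        pd.testing.assert_frame_equal(a.human_week12.values, b.human_week12.values)
        pd.testing.assert_frame_equal(a.dex_table, b.dex_table)
        pd.testing.assert_frame_equal(a.orthology.table, b.orthology.table)
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = simulate_mouse_cohort(small_config(seed=1))[0]
        b = simulate_mouse_cohort(small_config(seed=2))[0]
        assert not np.allclose(a.values.to_numpy(), b.values.to_numpy())


class TestMouseCohort:
    def test_study_group_sizes(self):
        cfg = small_config(n_good=12, n_poor=12, n_intermediate=0, n_vehicle=12)
        _, _, ann = simulate_mouse_cohort(cfg)
        counts = ann["responder"].value_counts()
        assert counts["good"] == 12 and counts["poor"] == 12 and counts["vehicle"] == 12

    def test_zero_contrast_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_mouse_cohort(small_config(n_good=0))

    def test_too_many_signal_probes_rejected(self):
        with pytest.raises(ValueError, match="n_signal_probes"):
            simulate_mouse_cohort(small_config(n_signal_probes=10_000))

    def test_truth_bookkeeping_and_detection_survival(self):
        blood, brain, ann = simulate_mouse_cohort(small_config())
        truth = ann.attrs["truth"]
        assert len(truth["signal_probes"]) == 40
        assert set(truth["signal_probes"]) <= set(blood.probe_ids)
        assert set(truth["signal_probes"].values()) <= {-1, 1}
        # planted probes survive the detection rule by construction
        detected = set(detection_filter(blood, MOUSE_DETECTION_RULE).probe_ids)
        assert set(truth["signal_probes"]) <= detected

    def test_planted_effect_magnitude(self):
        cfg = small_config(n_good=30, n_poor=30, n_intermediate=0, n_vehicle=0,
                           effect_blood=2.0, chip_sd=0.0, conc_slope=0.0)
        blood, _, ann = simulate_mouse_cohort(cfg)
        truth = ann.attrs["truth"]["signal_probes"]
        good = ann.loc[ann["responder"] == "good", "animal_id"]
        poor = ann.loc[ann["responder"] == "poor", "animal_id"]
        diffs = [
            (blood.values.loc[p, good].mean() - blood.values.loc[p, poor].mean()) * s
            for p, s in truth.items()
        ]
        # mean planted difference = effect * noise_sd = 1.0
        assert np.mean(diffs) == pytest.approx(1.0, abs=3 * 0.5 * np.sqrt(2 / 30 / 40) * 3)

    def test_floating_ranges_separate_groups(self):
        _, _, ann = simulate_mouse_cohort(small_config())
        good_max = ann.loc[ann["responder"] == "good", "floating_s"].max()
        poor_min = ann.loc[ann["responder"] == "poor", "floating_s"].min()
        inter = ann.loc[ann["responder"] == "intermediate", "floating_s"]
        assert good_max < inter.min() < inter.max() < poor_min

    def test_fst_time_budget(self):
        _, _, ann = simulate_mouse_cohort(small_config())
        total = ann["floating_s"] + ann["struggling_s"] + ann["swimming_s"]
        assert (total <= 300.0 + 0.3).all()

    def test_conc_missing_blanked(self):
        _, _, ann = simulate_mouse_cohort(small_config(conc_missing=4))
        treated = ann[ann["arm"] == "paroxetine"]
        assert treated["plasma_conc"].isna().sum() == 4
        assert treated["brain_conc"].notna().all()


class TestHumanCohort:
    def test_class_imbalance_achievable(self):
        # 86 patients at the study's responder fraction: labels follow the
        # >= 50 % HDRS improvement rule applied to the generated scores
        from respsig.phenotype import label_response

        base, week, ann = simulate_human_cohort(small_config(n_patients=86), [])
        labelled = label_response(ann)
        n_resp = labelled["responder"].sum()
        assert 2 <= n_resp <= 84
        assert set(labelled.loc[labelled["responder"], "patient_id"]) == set(
            ann.attrs["truth"]["planted_responders"]
        )

    def test_responder_fraction_calibrated(self):
        # marginal calibration over 200 seeds, 3 Monte-Carlo SE
        fracs = []
        for seed in range(200):
            cfg = small_config(seed=seed, n_probes_human=30, n_patients=40)
            _, _, ann = simulate_human_cohort(cfg, [])
            fracs.append(len(ann.attrs["truth"]["planted_responders"]) / 40)
        f = 63 / 86
        se = np.sqrt(f * (1 - f) / (200 * 40))
        assert abs(np.mean(fracs) - f) < 3 * se

    def test_extreme_fraction_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            simulate_human_cohort(small_config(responder_fraction=0.999), [])

    def test_unknown_signature_probe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            simulate_human_cohort(small_config(), ["nonexistent"])

    def test_null_effect_gives_identical_distributions(self):
        cfg = small_config(effect_human=0.0)
        base, week, ann = simulate_human_cohort(cfg, ["hsa_000000"])
        # no planted shift: responder and nonresponder deltas have the
        # same spread on the signature probe
        delta = (week.values - base.values).loc["hsa_000000"]
        resp = ann.attrs["truth"]["planted_responders"]
        non = [p for p in ann["patient_id"] if p not in resp]
        assert abs(delta[resp].mean() - delta[non].mean()) < 1.0


class TestDexExperiment:
    def test_perfect_concordance(self):
        cfg = small_config(dex_concordance=1.0)
        universe = [f"pr{i}" for i in range(300)]
        signs = {p: (1 if i % 2 else -1) for i, p in enumerate(universe[:50])}
        tab = simulate_dex_experiment(cfg, universe, signs)
        shared = tab[(tab["regulated"] == 1) & tab["probe_id"].isin(signs)]
        assert len(shared) > 0
        assert all(signs[p] == s for p, s in zip(shared["probe_id"], shared["sign"]))

    def test_overlap_mean_matches_closed_form(self):
        # boost 0: E[overlap] = |signature| * dex_fraction
        universe = [f"pr{i}" for i in range(400)]
        signs = {p: 1 for p in universe[:60]}
        overlaps = []
        for seed in range(200):
            cfg = small_config(seed=seed, dex_overlap_boost=0.0, dex_fraction=0.4)
            tab = simulate_dex_experiment(cfg, universe, signs)
            overlaps.append(
                ((tab["regulated"] == 1) & tab["probe_id"].isin(signs)).sum()
            )
        expected = 60 * 0.4
        se = np.sqrt(60 * 0.4 * 0.6 / 200)
        assert abs(np.mean(overlaps) - expected) < 3 * se

    def test_concordance_rate_calibrated(self):
        universe = [f"pr{i}" for i in range(400)]
        signs = {p: 1 for p in universe[:100]}
        rates = []
        for seed in range(200):
            cfg = small_config(seed=seed, dex_concordance=0.7)
            tab = simulate_dex_experiment(cfg, universe, signs)
            shared = tab[(tab["regulated"] == 1) & tab["probe_id"].isin(signs)]
            if len(shared):
                rates.append((shared["sign"] == 1).mean())
        se = np.sqrt(0.7 * 0.3 / (200 * 70))
        assert abs(np.mean(rates) - 0.7) < 3 * se + 0.01

    def test_overflow_capped_with_warning(self):
        cfg = small_config(dex_fraction=0.9, dex_overlap_boost=0.5)
        with pytest.warns(UserWarning, match="capping"):
            simulate_dex_experiment(cfg, ["a", "b"], {"a": 1})

    def test_paper_shaped_margins_constructible(self):
        cfg = small_config(
            n_probes_mouse=2852, dex_fraction=1882 / 2852, dex_overlap_boost=0.09
        )
        universe = [f"pr{i}" for i in range(2852)]
        signs = {p: 1 for p in universe[:179]}
        tab = simulate_dex_experiment(cfg, universe, signs)
        assert len(tab) == 2852
        k_reg = (tab["regulated"] == 1).sum()
        assert abs(k_reg - 1882) < 5 * np.sqrt(2852 * 0.66 * 0.34)


class TestOrthologyMap:
    def test_bijection_case(self):
        cfg = small_config(
            mapping_rate=1.0, probes_per_gene_mouse=1.0, probes_per_gene_human=1.0
        )
        mouse = [f"mp{i}" for i in range(50)]
        human = [f"hp{i}" for i in range(80)]
        omap = simulate_orthology_map(cfg, mouse, human)
        assert len(omap) == 50
        assert omap.table["mouse_probe"].is_unique
        assert omap.table["human_probe"].is_unique

    def test_zero_mapping_rate_gives_empty_map_and_clean_error(self):
        cfg = small_config(mapping_rate=0.0)
        omap = simulate_orthology_map(cfg, [f"mp{i}" for i in range(20)], ["hp0"])
        assert len(omap) == 0
        with pytest.raises(ValueError, match="nothing to classify"):
            map_signature_to_human(["mp0"], omap, ["hp0"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_orthology_map(small_config(), [], ["hp0"])

    def test_some_genes_multi_probe(self):
        cfg = small_config(probes_per_gene_mouse=1.3)
        omap = simulate_orthology_map(
            cfg, [f"mp{i}" for i in range(300)], [f"hp{i}" for i in range(600)]
        )
        per_gene = omap.table.groupby("mouse_gene")["mouse_probe"].nunique()
        assert (per_gene > 1).any()


class TestBundle:
    def test_bundle_consistency(self, small_bundle):
        b = small_bundle
        assert list(b.mouse_blood.sample_ids) == list(b.mouse_annotation["animal_id"])
        assert list(b.human_baseline.sample_ids) == list(b.human_week12.sample_ids)
        assert b.human_baseline.probe_ids.equals(b.human_week12.probe_ids)
        # human signature probes in truth are orthologues of planted mouse probes
        tab = b.orthology.table
        expected = set(
            tab[tab["mouse_probe"].isin(b.truth["signal_probes"])]["human_probe"]
        )
        assert set(b.truth["human_signature_probes"]) == expected

    def test_round_trip_tsv(self, small_bundle, tmp_path):
        from respsig.simulate import read_bundle, write_bundle

        write_bundle(small_bundle, tmp_path / "bundle")
        back = read_bundle(tmp_path / "bundle")
        np.testing.assert_allclose(
            back.mouse_blood.values.to_numpy(),
            small_bundle.mouse_blood.values.to_numpy(),
            rtol=1e-9,
        )
        assert back.truth["signal_probes"] == small_bundle.truth["signal_probes"]
        assert back.config == small_bundle.config
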