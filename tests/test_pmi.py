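"""Index construction, log-ratio scoring, ROC/cutoff logic, CV and transfer."""
import dataclasses
import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from psomi.core_io import to_relative
from psomi.diff_abundance import DifferentialFeature, lefse
from psomi.pmi import (IndexDefinition, apply_index, compute_pmi,
                       cross_validate, define_index, roc_curve, select_cutoff)
from psomi.synthetic import generate_cohort

from .conftest import make_metadata, make_table
from .oracles import oracle_auc

INDEX = IndexDefinition(frozenset({"Faecalibacterium", "Blautia"}),
                        frozenset({"Bacteroides", "Paraprevotella"}))


def feature(genus, direction):
    return DifferentialFeature(genus, direction, 0.01, 3.0)


class TestDefineIndex:
    def test_signature_features_split_by_direction(self):
        feats = [feature("Faecalibacterium", "case_enriched"),
                 feature("Blautia", "case_enriched"),
                 feature("Bacteroides", "control_enriched"),
                 feature("Paraprevotella", "control_enriched")]
        idx = define_index(feats)
        assert idx.increased_genera == {"Faecalibacterium", "Blautia"}
        assert idx.decreased_genera == {"Bacteroides", "Paraprevotella"}

    def test_one_sided_features_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            define_index([feature("Blautia", "case_enriched")])

    def test_genus_in_both_directions_rejected(self):
        with pytest.raises(ValueError, match="both"):
            define_index([feature("Blautia", "case_enriched"),
                          feature("Blautia", "control_enriched"),
                          feature("Bacteroides", "control_enriched")])

    def test_json_round_trip(self):
        again = IndexDefinition.from_json(INDEX.to_json())
        assert again == INDEX


class TestComputePmi:
    def _table(self, columns):
        taxa = ["Faecalibacterium", "Blautia", "Bacteroides",
                "Paraprevotella", "Other"]
        samples = [f"s{j}" for j in range(len(columns))]
        return make_table(np.array(columns).T, taxa, samples,
                          is_relative=True)

    def test_log_ratio_values(self):
        table = self._table([
            [0.01, 0.01, 0.10, 0.10, 0.78],   # num 0.02 / den 0.20 -> -1.0
            [0.10, 0.10, 0.10, 0.10, 0.60],   # equal sums -> 0
            [0.20, 0.20, 0.02, 0.02, 0.56],   # 0.40/0.04 -> +1.0
        ])
        scores = compute_pmi(table, INDEX)
        assert scores["s0"] == pytest.approx(-1.0)
        assert scores["s1"] == pytest.approx(0.0)
        assert scores["s2"] == pytest.approx(1.0)

    def test_swapping_directions_negates_scores(self):
        table = self._table([[0.05, 0.1, 0.2, 0.02, 0.63],
                             [0.3, 0.05, 0.07, 0.08, 0.5]])
        swapped = IndexDefinition(INDEX.decreased_genera,
                                  INDEX.increased_genera)
        np.testing.assert_allclose(compute_pmi(table, swapped),
                                   -compute_pmi(table, INDEX))

    def test_missing_genus_warns_and_contributes_zero(self):
        table = make_table(np.array([[0.4], [0.6]]),
                           ["Faecalibacterium", "Bacteroides"], ["s0"],
                           is_relative=True)
        with pytest.warns(UserWarning, match="Blautia"):
            scores = compute_pmi(table, INDEX)
        assert scores["s0"] == pytest.approx(np.log10(0.4 / 0.6))

    def test_counts_table_rejected_and_all_missing_is_error(self):
        counts = make_table([[4], [6]], ["Faecalibacterium", "Bacteroides"],
                            ["s0"])
        with pytest.raises(ValueError, match="relative"):
            compute_pmi(counts, INDEX)
        other = make_table([[1.0]], ["Other"], ["s0"], is_relative=True)
        with pytest.raises(ValueError, match="none", ):
            with pytest.warns(UserWarning):
                compute_pmi(other, INDEX)

    def test_zero_sum_samples_get_pseudocount(self):
        table = self._table([[0.0, 0.0, 0.2, 0.2, 0.6],
                             [0.2, 0.2, 0.0, 0.0, 0.6]])
        scores = compute_pmi(table, INDEX)
        assert np.isfinite(scores).all()
        assert scores["s0"] < 0 < scores["s1"]


class TestRocCurve:
    def test_perfect_separation(self):
        scores = [1.0, 2.0, 3.0, -1.0, -2.0]
        labels = ["case"] * 3 + ["control"] * 2
        rc = roc_curve(scores, labels)
        assert rc.auc == 1.0
        assert rc.sensitivity[0] == 0.0 and rc.sensitivity[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve([1.0, 2.0], ["case", "case"])

    def test_sensitivity_monotone_along_curve(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "case", "control")
        if len(set(labels)) < 2:
            labels[0] = "case"
            labels[1] = "control"
        rc = roc_curve(scores, labels)
        assert (np.diff(rc.sensitivity) >= 0).all()
        assert (np.diff(rc.specificity) <= 0).all()

    def test_auc_matches_exhaustive_concordance_with_ties(self):
        # every label split and tied-score configuration at small n
        for n in range(2, 7):
            for labels in itertools.product(["case", "control"], repeat=n):
                if len(set(labels)) < 2:
                    continue
                rng = np.random.default_rng(n * 1000 + hash(labels) % 1000)
                for _ in range(3):
                    scores = rng.integers(0, 3, size=n).astype(float)
                    got = roc_curve(scores, list(labels)).auc
                    want = oracle_auc(scores, labels)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_auc_agrees_with_sklearn(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        labels = ["case"] * 30 + ["control"] * 30
        got = roc_curve(scores, labels).auc
        ref = roc_auc_score([1] * 30 + [0] * 30, scores)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = ["case" if v > -0.2 else "control"
                  for v in scores + rng.normal(size=50)]
        if len(set(labels)) < 2:
            labels[0] = "case"
            labels[1] = "control"
        base = roc_curve(scores, labels).auc
        for transform in (lambda x: 3 * x + 2, np.tanh,
                          lambda x: np.exp(x / 2)):
            assert roc_curve(transform(np.asarray(scores)), labels).auc == \
                pytest.approx(base, abs=1e-12)


class TestSelectCutoff:
    def test_symmetric_clouds_cut_near_zero(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.normal(1.0, 1.0, 300), rng.normal(-1.0, 1.0, 300)]
        labels = ["case"] * 300 + ["control"] * 300
        cut = select_cutoff(roc_curve(scores, labels))
        assert abs(cut.threshold) < 0.3
        assert abs(cut.sensitivity - cut.specificity) <= 0.02

    def test_separated_scores_cut_in_the_gap(self):
        scores = [2.0, 3.0, 4.0, -1.0, 0.0]
        labels = ["case"] * 3 + ["control"] * 2
        cut = select_cutoff(roc_curve(scores, labels))
        assert cut.threshold == pytest.approx(1.0)  # midpoint of (0, 2)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0

    def test_gap_is_minimal_over_all_thresholds(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=80)
        labels = ["case" if v + rng.normal() > 0 else "control"
                  for v in scores]
        if len(set(labels)) < 2:
            labels[:2] = ["case", "control"]
        rc = roc_curve(scores, labels)
        cut = select_cutoff(rc)
        gaps = np.abs(rc.sensitivity - rc.specificity)
        assert abs(cut.sensitivity - cut.specificity) <= gaps.min() + 1e-12


@pytest.fixture(scope="module")
def scored_cohort(default_cohort):
    _, table, md, _ = default_cohort
    rel = to_relative(table)
    return rel, md


class TestCrossValidate:
    def test_frozen_index_pooled_auc_equals_full_data_auc(self, scored_cohort):
        rel, md = scored_cohort
        cv = cross_validate(rel, md, k=5, seed=0, reselect=False, index=INDEX)
        scores = compute_pmi(rel, INDEX)
        full = roc_curve(scores.to_numpy(),
                         md.groups.reindex(scores.index).to_numpy())
        assert cv.roc.auc == pytest.approx(full.auc)

    def test_fold_assignment_reproducible_and_stratified(self, scored_cohort):
        rel, md = scored_cohort
        cv1 = cross_validate(rel, md, k=5, seed=3, reselect=False, index=INDEX)
        cv2 = cross_validate(rel, md, k=5, seed=3, reselect=False, index=INDEX)
        assert cv1.fold_assignments.equals(cv2.fold_assignments)
        groups = md.groups
        for fold in range(5):
            members = cv1.fold_assignments[cv1.fold_assignments == fold].index
            cases = (groups.loc[members] == "case").sum()
            assert abs(cases - len(members) / 2) <= 1

    def test_reselection_recovers_discriminative_index(self, scored_cohort):
        rel, md = scored_cohort
        cv = cross_validate(rel, md, k=10, seed=1, reselect=True)
        assert cv.roc.auc >= 0.85
        for idx in cv.fold_indices:
            assert {"Faecalibacterium", "Blautia"} <= idx.increased_genera

    def test_class_smaller_than_k_rejected(self, scored_cohort):
        rel, md = scored_cohort
        with pytest.raises(ValueError, match="k <="):
            cross_validate(rel, md, k=60, reselect=False, index=INDEX)


class TestApplyIndex:
    def test_self_application_reproduces_training_metrics(self, scored_cohort):
        rel, md = scored_cohort
        scores = compute_pmi(rel, INDEX)
        labels = md.groups.reindex(scores.index).to_numpy()
        rc = roc_curve(scores.to_numpy(), labels)
        cut = select_cutoff(rc)
        ev = apply_index(rel, INDEX, cut.threshold, md)
        assert ev.provenance == "external"
        assert ev.sensitivity == pytest.approx(cut.sensitivity)
        assert ev.specificity == pytest.approx(cut.specificity)
        assert ev.auc == pytest.approx(rc.auc)

    def test_transfer_to_same_model_cohort(self, default_cohort):
        cfg, table, md, _ = default_cohort
        rel = to_relative(table)
        scores = compute_pmi(rel, INDEX)
        cut = select_cutoff(roc_curve(
            scores.to_numpy(), md.groups.reindex(scores.index).to_numpy()))
        ext_cfg = dataclasses.replace(cfg, seed=cfg.seed + 5000)
        etable, emd, _ = generate_cohort(ext_cfg)
        ev = apply_index(to_relative(etable), INDEX, cut.threshold, emd)
        assert abs(ev.sensitivity - cut.sensitivity) <= 0.15
        assert abs(ev.specificity - cut.specificity) <= 0.15

    def test_inverted_effects_flip_the_auc(self, default_cohort):
        cfg, _, _, _ = default_cohort
        inverted = dataclasses.replace(
            cfg, seed=999,
            effect_multipliers={g: 1.0 / m
                                for g, m in cfg.effect_multipliers.items()})
        table, md, _ = generate_cohort(inverted)
        ev = apply_index(to_relative(table), INDEX, cutoff=0.0, test_md=md)
        assert ev.auc < 0.5


class TestAntiSymmetry:
    def test_direction_swap_negates_scores_and_flips_auc(self, scored_cohort):
        rel, md = scored_cohort
        swapped = IndexDefinition(INDEX.decreased_genera,
                                  INDEX.increased_genera)
        s1 = compute_pmi(rel, INDEX)
        s2 = compute_pmi(rel, swapped)
        np.testing.assert_allclose(s2.to_numpy(), -s1.to_numpy(), atol=1e-12)
        labels = md.groups.reindex(s1.index).to_numpy()
        a1 = roc_curve(s1.to_numpy(), labels).auc
        a2 = roc_curve(s2.to_numpy(), labels).auc
        assert a1 + a2 == pytest.approx(1.0)
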