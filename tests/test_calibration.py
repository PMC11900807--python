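"""ROC/AUC, enrichment factors, threshold optimization and calibration."""

import numpy as np
import pytest

from conftest import brute_force_auc, labels_by_rank, make_ranked, random_instance
from orscreen.calibration import (
    ACTIVE,
    INACTIVE,
    NON_PHEROMONAL,
    PHEROMONE,
    ActivityMatrix,
    calibrate,
    enrichment_factor,
    max_enrichment_factor,
    optimal_top_fraction,
    roc_auc,
    top_k,
    tpr_saturation_rank,
)
from orscreen.rescoring import RAW_METHOD, ScoreTable


class TestRocAuc:
    def test_perfect_and_inverted_separation(self):
        rl = make_ranked({"a": -9.0, "b": -8.0, "c": -2.0, "d": -1.0})
        assert roc_auc(rl, labels_by_rank(rl, {1, 2})) == 1.0
        assert roc_auc(rl, labels_by_rank(rl, {3, 4})) == 0.0

    def test_pair_enumeration_example(self):
        rl = make_ranked({"a": -9.0, "b": -5.0, "c": -4.0, "d": -1.0})
        labels = {"a": ACTIVE, "b": INACTIVE, "c": ACTIVE, "d": INACTIVE}
        assert roc_auc(rl, labels) == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_tied_scores_get_half_credit(self):
        rl = make_ranked({"a": -5.0, "b": -5.0})
        assert roc_auc(rl, {"a": ACTIVE, "b": INACTIVE}) == pytest.approx(0.5)

    def test_degenerate_labels_raise(self):
        rl = make_ranked({"a": -5.0, "b": -4.0})
        with pytest.raises(ValueError):
            roc_auc(rl, {"a": ACTIVE, "b": ACTIVE})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            scores, labels = random_instance(rng)
            rl = make_ranked(scores)
            assert roc_auc(rl, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_reversal_identity_without_ties(self):
        """AUC(ranking) + AUC(reversed) = 1 when scores are distinct."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = {f"m{i}": float(s) for i, s in enumerate(rng.permutation(n) - n)}
            labels = {m: (ACTIVE if rng.random() < 0.4 else INACTIVE) for m in scores}
            if len(set(labels.values())) < 2:
                continue
            fwd = roc_auc(make_ranked(scores), labels)
            rev = roc_auc(make_ranked({m: -s for m, s in scores.items()}), labels)
            assert fwd + rev == pytest.approx(1.0)


class TestEnrichmentFactor:
    def _uniform(self, n=100, n_act=10, top_act=5):
        """n molecules, n_act actives, top_act of them in the top 10%."""
        scores = {f"m{i:03d}": -float(n - i) for i in range(n)}
        rl = make_ranked(scores)
        k = 10
        active_ranks = set(range(1, top_act + 1)) | set(
            range(n - (n_act - top_act) + 1, n + 1)
        )
        return rl, labels_by_rank(rl, active_ranks)

    def test_counting_example(self):
        rl, labels = self._uniform()
        assert enrichment_factor(rl, labels, 0.10) == pytest.approx(5.0)

    def test_maximal_enrichment(self):
        scores = {f"m{i:03d}": -float(100 - i) for i in range(100)}
        rl = make_ranked(scores)
        labels = labels_by_rank(rl, set(range(1, 11)))
        assert enrichment_factor(rl, labels, 0.10) == pytest.approx(10.0)

    def test_uniform_spread_is_unenriched(self):
        scores = {f"m{i:03d}": -float(100 - i) for i in range(100)}
        rl = make_ranked(scores)
        labels = labels_by_rank(rl, set(range(5, 101, 10)))  # one active per decile
        assert enrichment_factor(rl, labels, 0.10) == pytest.approx(1.0)

    def test_ef_at_full_fraction_is_one(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores, labels = random_instance(rng)
            if not any(v == ACTIVE for v in labels.values()):
                continue
            assert enrichment_factor(make_ranked(scores), labels, 1.0) == pytest.approx(1.0)

    def test_zero_actives_raise(self):
        rl = make_ranked({"a": -2.0, "b": -1.0})
        with pytest.raises(ValueError):
            enrichment_factor(rl, {"a": INACTIVE, "b": INACTIVE}, 0.5)

    def test_max_ef_agrees_with_grid_scan(self):
        rng = np.random.default_rng(9)
        grid = [round(f, 2) for f in np.arange(0.01, 1.001, 0.01)]
        for _ in range(20):
            scores, labels = random_instance(rng)
            if not any(v == ACTIVE for v in labels.values()):
                continue
            rl = make_ranked(scores)
            slow = max(enrichment_factor(rl, labels, f) for f in grid)
            assert max_enrichment_factor(rl, labels, grid) == pytest.approx(slow)

    def test_max_ef_bounded_by_inverse_prevalence(self):
        rl, labels = self._uniform()
        n_act = sum(v == ACTIVE for v in labels.values())
        assert max_enrichment_factor(rl, labels) <= len(rl) / n_act + 1e-9


def test_top_k_round_half_up():
    assert top_k(0.06, 51) == 3       # 3.06 -> 3
    assert top_k(0.05, 50) == 3       # 2.5 rounds up
    assert top_k(0.001, 100) == 1     # floor of 1
    assert top_k(1.0, 7) == 7


class TestOptimalTopFraction:
    def test_hand_enumerated_grid(self):
        """Actives at ranks 1-2 of 10: TPR saturates at 20% while the
        continuity-corrected FPR stays 0.5/8, giving ratio 16."""
        scores = {f"m{i}": -float(10 - i) for i in range(10)}
        rl = make_ranked(scores)
        labels = labels_by_rank(rl, {1, 2})
        grid = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        frac, ratio = optimal_top_fraction(rl, labels, grid)
        assert frac == pytest.approx(0.2)
        assert ratio == pytest.approx(1.0 / (0.5 / 8))  # 16

    def test_worst_ranked_actives_need_full_list(self):
        scores = {f"m{i}": -float(10 - i) for i in range(10)}
        rl = make_ranked(scores)
        labels = labels_by_rank(rl, {9, 10})
        frac, _ = optimal_top_fraction(rl, labels, [0.2, 0.5, 1.0])
        assert frac == 1.0

    def test_single_grid_value(self):
        scores = {f"m{i}": -float(4 - i) for i in range(4)}
        rl = make_ranked(scores)
        frac, _ = optimal_top_fraction(rl, labels_by_rank(rl, {1}), [0.25])
        assert frac == 0.25


def test_tpr_saturation_rank_is_worst_active_rank():
    scores = {f"m{i}": -float(10 - i) for i in range(10)}
    rl = make_ranked(scores)
    assert tpr_saturation_rank(rl, labels_by_rank(rl, {2, 5})) == 5


class TestActivityMatrix:
    def test_p_value_thresholding_strict(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "receptor": ["R1"] * 3,
                "molecule": ["a", "b", "c"],
                "p_value": [0.0005, 0.001, 0.2],
            }
        )
        am = ActivityMatrix.from_frame(df)
        assert am.labels[("R1", "a")] == ACTIVE
        assert am.labels[("R1", "b")] == INACTIVE  # p == threshold is inactive
        assert am.labels[("R1", "c")] == INACTIVE

    def test_labels_take_precedence_and_validate(self):
        import pandas as pd

        df = pd.DataFrame({"receptor": ["R1"], "molecule": ["a"], "label": ["maybe"]})
        with pytest.raises(ValueError, match="maybe"):
            ActivityMatrix.from_frame(df)


class TestCalibrate:
    def _panel(self, n_receptors=5, n=100, seed=0, classes=None):
        """Constructed panel: method 'good' separates perfectly, 'bad'
        is anti-correlated."""
        rng = np.random.default_rng(seed)
        tables, labels = {}, {}
        for i in range(n_receptors):
            rec = f"R{i}"
            actives = set(rng.choice(n, size=10, replace=False))
            good = {f"m{j:03d}": (-100.0 + j if j in actives else -float(j) / n) for j in range(n)}
            bad = {m: -s for m, s in good.items()}
            tables[rec] = {
                "good": ScoreTable(rec, RAW_METHOD, good),
                "bad": ScoreTable(rec, RAW_METHOD, bad),
            }
            for j in range(n):
                labels[(rec, f"m{j:03d}")] = ACTIVE if j in actives else INACTIVE
        classes = classes or {f"R{i}": NON_PHEROMONAL for i in range(n_receptors)}
        return tables, ActivityMatrix(receptor_class=classes, labels=labels)

    def test_perfect_method_has_median_auc_one(self):
        tables, activity = self._panel()
        report = calibrate(tables, activity)
        assert report.median_auc[(NON_PHEROMONAL, "good")] == 1.0
        assert report.chosen_method == "good"
        assert report.median_auc[(NON_PHEROMONAL, "bad")] == 0.0

    def test_chosen_fraction_is_median_of_optima(self):
        tables, activity = self._panel()
        report = calibrate(tables, activity)
        optima = report.per_receptor.query("method == 'good'")["optimal_fraction"]
        assert report.chosen_top_fraction == float(np.median(optima))

    def test_pheromone_receptors_excluded_from_thresholds(self):
        classes = {"R0": PHEROMONE, "R1": NON_PHEROMONAL, "R2": NON_PHEROMONAL,
                   "R3": NON_PHEROMONAL, "R4": NON_PHEROMONAL}
        tables, activity = self._panel(classes=classes)
        report = calibrate(tables, activity)
        pool = report.per_receptor.query("method == @report.chosen_method")
        pool = pool[pool["receptor_class"] == NON_PHEROMONAL]
        assert "R0" not in set(pool["receptor"])
        assert report.chosen_top_fraction == float(np.median(pool["optimal_fraction"]))

    def test_missing_table_raises(self):
        tables, activity = self._panel()
        del tables["R0"]["bad"]
        with pytest.raises(KeyError):
            calibrate(tables, activity)

    def test_nonbinder_fraction_median_of_saturation_ranks(self):
        """Receptors whose worst active sits at ranks 40/45/50 of 100
        give a non-binder fraction of 0.45."""
        tables, labels = {}, {}
        for rec, worst in (("R0", 40), ("R1", 45), ("R2", 50)):
            scores = {f"m{j:03d}": -float(100 - j) for j in range(100)}
            tables[rec] = {"good": ScoreTable(rec, RAW_METHOD, scores)}
            rl_ranks = {1, worst}
            order = sorted(scores, key=lambda m: (scores[m], m))
            for j, m in enumerate(order, start=1):
                labels[(rec, m)] = ACTIVE if j in rl_ranks else INACTIVE
        activity = ActivityMatrix(
            receptor_class={r: NON_PHEROMONAL for r in tables}, labels=labels
        )
        report = calibrate(tables, activity, select_method="good")
        assert report.nonbinder_fraction == pytest.approx(0.45)

    def test_report_serializes(self):
        import json

        tables, activity = self._panel(n_receptors=3)
        report = calibrate(tables, activity)
        payload = json.loads(report.to_json())
        assert payload["chosen_method"] == "good"
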