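"""Agreement, consensus, sensitivity/specificity, ROC and AUC statistics."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st
from scipy import stats

from nutridss.errors import (
    AlignmentError,
    ClassBalanceError,
    IncompleteConsensusError,
)
from nutridss.validation import (
    GoldStandard,
    LabelSet,
    agreement_rate,
    auc,
    auc_ci,
    auc_se,
    build_consensus,
    roc_curve,
    sensitivity_specificity,
    validate_system,
)


def labelset(rater, labels):
    return LabelSet(rater, {(f"c{i}", "d"): lab for i, lab in enumerate(labels)})


def paired_sets(n_match, n_total):
    a = {(f"c{i}", "d"): "present" for i in range(n_total)}
    b = dict(a)
    for i in range(n_total - n_match):
        b[(f"c{i}", "d")] = "absent"
    return LabelSet("a", a), LabelSet("b", b)


class TestAgreement:
    @pytest.mark.parametrize(
        "count,total,percent",
        [(54, 60, 90), (56, 60, 93), (48, 60, 80), (52, 60, 87), (55, 60, 92)],
    )
    def test_published_assertiveness_arithmetic(self, count, total, percent):
        a, b = paired_sets(count, total)
        result = agreement_rate(a, b)
        assert (result.count, result.total) == (count, total)
        assert result.percent == pytest.approx(100 * count / total)
        assert result.percent_rounded == percent

    def test_identical_sets_agree_fully(self):
        a, b = paired_sets(60, 60)
        result = agreement_rate(a, b)
        assert (result.count, result.total, result.percent) == (60, 60, 100.0)

    def test_symmetry(self):
        a, b = paired_sets(40, 60)
        assert agreement_rate(a, b) == agreement_rate(b, a)

    def test_misaligned_keys_raise_with_listing(self):
        a = LabelSet("a", {("c1", "d"): "present"})
        b = LabelSet("b", {("c2", "d"): "present"})
        with pytest.raises(AlignmentError) as exc:
            agreement_rate(a, b)
        assert exc.value.missing_in_a == {("c2", "d")}

    def test_empty_input_raises(self):
        with pytest.raises(AlignmentError):
            agreement_rate(LabelSet("a", {}), LabelSet("b", {}))

    @given(st.lists(st.sampled_from(["present", "at_risk", "absent"]), min_size=1, max_size=30))
    def test_exact_match_on_three_state_scale(self, labels):
        # at_risk vs present is a disagreement, not a near-miss
        a = labelset("a", labels)
        b = labelset("b", ["at_risk" if x == "present" else x for x in labels])
        expected = sum(x != "present" for x in labels)
        assert agreement_rate(a, b).count == expected


class TestConsensus:
    def test_unanimous(self):
        panel = [labelset(f"r{i}", ["at_risk"] * 3) for i in range(4)]
        gold = build_consensus(panel)
        assert set(gold.labels.values()) == {"at_risk"}
        assert set(gold.provenance.values()) == {"unanimous"}

    def test_strict_majority(self):
        panel = [
            labelset("r1", ["present"]),
            labelset("r2", ["present"]),
            labelset("r3", ["present"]),
            labelset("r4", ["absent"]),
        ]
        gold = build_consensus(panel)
        assert gold.labels[("c0", "d")] == "present"
        assert gold.provenance[("c0", "d")] == "majority"

    def test_two_two_tie_requires_adjudication(self):
        panel = [
            labelset("r1", ["present"]),
            labelset("r2", ["present"]),
            labelset("r3", ["absent"]),
            labelset("r4", ["absent"]),
        ]
        gold = build_consensus(panel)
        assert gold.pending == {("c0", "d")}
        with pytest.raises(IncompleteConsensusError):
            gold.require_complete()
        resolved = build_consensus(panel, adjudication={("c0", "d"): "present"})
        assert resolved.labels[("c0", "d")] == "present"
        assert resolved.provenance[("c0", "d")] == "adjudicated"
        resolved.require_complete()

    def test_single_rater_idempotent(self):
        rater = labelset("solo", ["present", "absent", "at_risk"])
        gold = build_consensus([rater])
        assert gold.labels == rater.labels
        assert not gold.pending

    def test_misaligned_panel_raises(self):
        with pytest.raises(AlignmentError):
            build_consensus([labelset("a", ["present"]), LabelSet("b", {("cX", "d"): "present"})])


class TestSensitivitySpecificity:
    def test_perfect_agreement(self):
        labels = {("c%d" % i, "d"): ("present" if i < 3 else "absent") for i in range(6)}
        system = LabelSet("sys", labels)
        gold = build_consensus([LabelSet("gold", dict(labels))])
        res = sensitivity_specificity(system, gold, "d")
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_printed_operating_point_magnitude(self):
        # TP=19, FN=1, TN=19, FP=1 -> sens 95.0, spec 95.0
        labels = {}
        system = {}
        for i in range(20):
            labels[(f"p{i}", "d")] = "present"
            system[(f"p{i}", "d")] = "present" if i else "absent"  # one FN
        for i in range(20):
            labels[(f"n{i}", "d")] = "absent"
            system[(f"n{i}", "d")] = "absent" if i else "at_risk"  # one FP
        res = sensitivity_specificity(
            LabelSet("sys", system), build_consensus([LabelSet("g", labels)]), "d"
        )
        assert res.confusion == {"TP": 19, "FP": 1, "TN": 19, "FN": 1}
        assert res.sensitivity == pytest.approx(95.0)
        assert res.specificity == pytest.approx(95.0)

    def test_at_risk_counts_as_positive(self):
        labels = {("c0", "d"): "at_risk", ("c1", "d"): "absent"}
        res = sensitivity_specificity(
            LabelSet("sys", labels), build_consensus([LabelSet("g", dict(labels))]), "d"
        )
        assert res.confusion["TP"] == 1 and res.confusion["TN"] == 1

    def test_all_negative_gold_leaves_sensitivity_undefined(self):
        labels = {(f"c{i}", "d"): "absent" for i in range(5)}
        res = sensitivity_specificity(
            LabelSet("sys", dict(labels)), build_consensus([LabelSet("g", labels)]), "d"
        )
        assert res.sensitivity is None
        assert "no positive" in " ".join(res.notes)
        assert res.specificity == 100.0


class TestRocCurve:
    def test_perfect_separation_passes_through_0_1(self):
        pairs = [(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]
        pts = roc_curve(pairs)
        assert [0.0, 1.0] in pts.tolist()
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        assert auc(pts) == 1.0

    def test_all_tied_scores_collapse_to_diagonal(self):
        pts = roc_curve([(0.5, 1), (0.5, 0), (0.5, 1), (0.5, 0)])
        assert pts.tolist() == [[0.0, 0.0], [1.0, 1.0]]
        assert auc(pts) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ClassBalanceError):
            roc_curve([(0.4, 1), (0.9, 1)])

    def test_matches_exhaustive_threshold_sweep(self):
        # oracle: classify positive at every candidate threshold directly
        pairs = [(0.9, 1), (0.7, 0), (0.7, 1), (0.4, 1), (0.3, 0), (0.1, 0)]
        scores = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        expected = {(0.0, 0.0)}
        for t in np.unique(scores):
            pred = scores >= t
            tpr = (pred & (y == 1)).sum() / (y == 1).sum()
            fpr = (pred & (y == 0)).sum() / (y == 0).sum()
            expected.add((round(fpr, 12), round(tpr, 12)))
        got = {(round(f, 12), round(t, 12)) for f, t in roc_curve(pairs)}
        assert got == expected


class TestAuc:
    def test_perfect_separation_auc_and_zero_se(self):
        pts = roc_curve([(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)])
        area = auc(pts)
        assert area == 1.0
        assert auc_se(area, 2, 2) == 0.0

    def test_hanley_mcneil_closed_form(self):
        # A=0.75, n_pos=n_neg=4: Q1=0.6, Q2=0.642857...,
        # SE = sqrt((0.1875 + 3*0.0375 + 3*0.0803571)/16) = 0.18389 (hand computed)
        assert auc_se(0.75, 4, 4) == pytest.approx(0.18389, abs=1e-4)

    def test_se_requires_both_classes(self):
        with pytest.raises(ClassBalanceError):
            auc_se(0.9, 0, 10)

    def test_ci_clipped_and_contains_auc(self):
        lo, hi = auc_ci(0.95, 0.1)
        assert lo == pytest.approx(0.95 - 1.96 * 0.1)
        assert hi == 1.0
        assert lo <= 0.95 <= hi

    @given(st.integers(0, 500))
    def test_complement_under_score_negation(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.arange(20, dtype=float))  # tie-free
        y = (rng.random(20) < 0.5).astype(int)
        assume(0 < y.sum() < 20)
        a = auc(roc_curve(list(zip(scores, y))))
        b = auc(roc_curve(list(zip(-scores, y))))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 500))
    def test_equals_mann_whitney_u_statistic(self, seed):
        """AUC == U/(n_pos*n_neg), midranks handling ties (independent oracle)."""
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(2, 15)), int(rng.integers(2, 15))
        if rng.random() < 0.5:  # force ties half the time
            pos = rng.integers(0, 5, n_pos).astype(float)
            neg = rng.integers(0, 5, n_neg).astype(float)
        else:
            pos = rng.normal(1, 1, n_pos)
            neg = rng.normal(0, 1, n_neg)
        pairs = [(s, 1) for s in pos] + [(s, 0) for s in neg]
        area = auc(roc_curve(pairs))
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert area == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_permutation_null_mean_near_half(self):
        rng = np.random.default_rng(11)
        n = 60
        areas = []
        for _ in range(300):
            scores = rng.normal(size=2 * n)
            y = np.array([1] * n + [0] * n)
            rng.shuffle(y)
            areas.append(auc(roc_curve(list(zip(scores, y)))))
        assert abs(np.mean(areas) - 0.5) < 0.02


class TestValidateSystem:
    def _grid(self):
        labels = {}
        rng = np.random.default_rng(5)
        for d in ("d1", "d2"):
            for i in range(15):
                labels[(f"c{i}", d)] = ["present", "at_risk", "absent"][int(rng.integers(3))]
        return labels

    def test_identical_system_and_gold(self):
        labels = self._grid()
        gold = build_consensus([LabelSet("g", dict(labels))])
        scores = {k: {"present": 0.9, "at_risk": 0.7, "absent": 0.1}[v] for k, v in labels.items()}
        result = validate_system(LabelSet("sys", dict(labels)), gold, scores=scores)
        assert result.overall_agreement.percent == 100.0
        for dv in result.per_diagnosis.values():
            assert dv.agreement.percent == 100.0
            assert dv.operating_point.sensitivity == 100.0
            assert dv.auc == 1.0  # scores separate classes perfectly
            assert dv.auc_se == 0.0
            lo, hi = dv.auc_ci95
            assert 0.0 <= lo <= dv.auc <= hi <= 1.0

    def test_single_class_diagnosis_records_error(self):
        labels = {(f"c{i}", "d"): "absent" for i in range(10)}
        gold = build_consensus([LabelSet("g", dict(labels))])
        scores = {k: 0.2 for k in labels}
        result = validate_system(LabelSet("sys", dict(labels)), gold, scores=scores)
        dv = result.per_diagnosis["d"]
        assert dv.error is not None and dv.auc is None

    def test_serializable(self):
        import json

        labels = self._grid()
        gold = build_consensus([LabelSet("g", dict(labels))])
        result = validate_system(LabelSet("sys", dict(labels)), gold)
        json.dumps(result.to_dict())
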