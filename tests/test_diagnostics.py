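"""ROC machinery, cutoff optimization, contingency statistics, paired AUC
comparison, multiplicity adjustment, rule-based calls and concordance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fetpwi.diagnostics import (
    POD,
    TRC,
    ContingencyTable,
    CutoffClassifier,
    MetricOrientation,
    ThresholdRuleClassifier,
    ThresholdRules,
    apply_thresholds,
    auc_ci,
    benjamini_hochberg,
    concordance_summary,
    contingency_metrics,
    format_performance,
    hanley_compare,
    hanley_mcneil_se,
    mann_whitney_auc,
    optimal_cutoff,
    roc_curve,
)


def brute_force_auc(scores, y):
    """Concordant-pair oracle: all POD/TRC pairs, half credit for ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(seed, max_n=40):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, max_n)
    # discretized scores so ties occur
    scores = np.round(rng.normal(size=n), 1)
    y = rng.integers(0, 2, size=n)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == y.size:
        y[0] = 0
    labels = np.where(y == 1, POD, TRC)
    return scores, y, labels


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([3.0, 2.9, 1.0, 0.9], [POD, POD, TRC, TRC])
        assert roc.auc == 1.0

    def test_uninformative_constant_scores(self):
        roc = roc_curve([2.0] * 6, [POD, POD, POD, TRC, TRC, TRC])
        assert roc.auc == pytest.approx(0.5)

    def test_concordant_pair_example(self):
        roc = roc_curve([2.9, 2.0, 2.5, 1.8], [POD, POD, TRC, TRC])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_spans_extremes(self):
        roc = roc_curve([2.9, 2.0, 2.5, 1.8], [POD, POD, TRC, TRC])
        pts = set(zip(roc.sensitivity.round(9), roc.specificity.round(9)))
        assert (0.0, 1.0) in pts and (1.0, 0.0) in pts

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [POD, POD])

    def test_orientation_flip(self):
        # lower-indicates-POD metrics are internally sign-flipped
        lo = roc_curve(
            [-2.9, -2.0, -2.5, -1.8],
            [POD, POD, TRC, TRC],
            MetricOrientation("m", higher_indicates_pod=False),
        )
        assert lo.auc == pytest.approx(0.75)

    @given(seed=st.integers(0, 10_000))
    def test_auc_equals_brute_force_oracle(self, seed):
        scores, y, labels = random_instance(seed)
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_oracle_agreement_at_n200(self):
        scores, y, labels = random_instance(424243, max_n=41)
        scores = np.tile(scores, 5)[:200]
        y = np.tile(y, 5)[:200]
        labels = np.where(y == 1, POD, TRC)
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)


class TestAucCi:
    def test_null_auc_gives_half_p(self):
        _, _, p = auc_ci(0.5, 20, 20)
        assert p == pytest.approx(0.5)

    def test_hanley_mcneil_closed_form(self):
        # hand-evaluated SE formula
        a, n1, n0 = 0.9, 42, 38
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        expected = np.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a))
            / (n1 * n0)
        )
        se, ci, p = auc_ci(a, n1, n0)
        assert se == pytest.approx(expected, abs=1e-15)
        assert ci[0] == pytest.approx(max(0.0, a - 1.96 * se))
        assert ci[1] == pytest.approx(min(1.0, a + 1.96 * se))

    def test_se_shrinks_with_n(self):
        ses = [auc_ci(0.8, n, n)[0] for n in (10, 40, 160, 640)]
        assert all(a > b for a, b in zip(ses, ses[1:]))


class TestOptimalCutoff:
    def test_perfect_separation_gmean_one(self):
        roc = roc_curve([3.0, 2.9, 1.0, 0.9], [POD, POD, TRC, TRC])
        cut = optimal_cutoff(roc)
        assert cut.gmean == pytest.approx(1.0)
        assert 1.0 < cut.threshold < 2.9

    def test_worked_example(self):
        roc = roc_curve([2.9, 2.0, 2.5, 1.8], [POD, POD, TRC, TRC])
        cut = optimal_cutoff(roc)
        assert cut.gmean == pytest.approx(np.sqrt(0.5))
        assert cut.threshold == pytest.approx(1.9)
        assert cut.direction == ">"

    def test_lower_oriented_cutoff_maps_back(self):
        roc = roc_curve(
            [-2.9, -2.0, -2.5, -1.8],
            [POD, POD, TRC, TRC],
            MetricOrientation("m", higher_indicates_pod=False),
        )
        cut = optimal_cutoff(roc)
        assert cut.direction == "<"
        assert cut.threshold == pytest.approx(-1.9)
        assert cut.call(-2.5) == POD
        assert cut.call(-1.5) == TRC

    @pytest.mark.parametrize("block", range(4))
    def test_equals_exhaustive_search(self, block):
        # 200 seeded random instances in 4 blocks
        for seed in range(block * 50, block * 50 + 50):
            scores, y, labels = random_instance(seed)
            roc = roc_curve(scores, labels)
            cut = optimal_cutoff(roc)
            # independent exhaustive oracle over every midpoint candidate
            distinct = np.unique(scores)
            cands = np.concatenate(
                [[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]]
            )
            best = -1.0
            for c in cands:
                pred = scores > c
                sens = (pred & (y == 1)).sum() / y.sum()
                spec = (~pred & (y == 0)).sum() / (y.size - y.sum())
                best = max(best, np.sqrt(sens * spec))
            assert cut.gmean == pytest.approx(best, abs=1e-12)
            # the returned operating point is achieved by its own threshold
            pred = scores > cut.threshold
            sens = (pred & (y == 1)).sum() / y.sum()
            spec = (~pred & (y == 0)).sum() / (y.size - y.sum())
            assert cut.sensitivity == pytest.approx(sens)
            assert cut.specificity == pytest.approx(spec)


class TestContingencyMetrics:
    def test_overall_performance_column(self):
        t = ContingencyTable(tp=36, fp=5, tn=33, fn=6)
        f = format_performance(contingency_metrics(t))
        assert f == {
            "accuracy": "86%",
            "sensitivity": "86%",
            "specificity": "87%",
            "ppv": "88%",
            "npv": "85%",
            "fpr": "13%",
            "fnr": "14%",
            "plr": "6.5",
            "nlr": "0.16",
        }

    def test_metastasis_column(self):
        t = ContingencyTable(tp=8, fp=3, tn=25, fn=2)
        f = format_performance(contingency_metrics(t))
        assert f["sensitivity"] == "80%"
        assert f["accuracy"] == "87%"

    def test_high_grade_glioma_column_count_derived(self):
        # The count-derived specificity is 8/10 = 80%; some published
        # summaries print inconsistent rounded values, so counts win.
        t = ContingencyTable(tp=28, fp=2, tn=8, fn=4)
        f = format_performance(contingency_metrics(t))
        assert f["specificity"] == "80%"
        assert f["sensitivity"] == "88%"
        assert f["ppv"] == "93%"
        assert f["plr"] == "4.4"

    def test_degenerate_all_positive(self):
        t = ContingencyTable(tp=7, fp=0, tn=0, fn=0)
        m = contingency_metrics(t)
        assert m["sensitivity"] == 1.0
        assert m["accuracy"] == 1.0
        assert m["specificity"] is None  # undefined, no TRC cases

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            ContingencyTable(tp=0, fp=0, tn=0, fn=0)

    @given(
        tp=st.integers(0, 30), fp=st.integers(0, 30),
        tn=st.integers(0, 30), fn=st.integers(0, 30),
    )
    def test_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        t = ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)
        m = contingency_metrics(t)
        if m["sensitivity"] is not None and m["specificity"] is not None:
            prev = (tp + fn) / t.n
            assert m["accuracy"] == pytest.approx(
                prev * m["sensitivity"] + (1 - prev) * m["specificity"]
            )
        if m["fpr"] is not None and m["specificity"] is not None:
            assert m["fpr"] == pytest.approx(1 - m["specificity"])
        if m["fnr"] is not None and m["sensitivity"] is not None:
            assert m["fnr"] == pytest.approx(1 - m["sensitivity"])


class TestApplyThresholds:
    def test_worked_case_ktrans_fires_rcbv_borderline(self):
        d = apply_thresholds(
            {"tbr_max": 2.75, "tbr_mean": 2.3, "ktrans": 0.38, "rcbv": 3.0}
        )
        assert d.pet_call == POD
        assert d.fired["mri:ktrans>0.26"] is True
        assert d.fired["mri:rcbv>3.0"] is False
        assert d.mri_call == POD
        assert d.hybrid_call == POD
        assert not d.discordant

    def test_exact_threshold_values_do_not_fire(self):
        d = apply_thresholds({"tbr_max": 2.5, "ktrans": 0.26, "rcbv": 3.0})
        assert (d.pet_call, d.mri_call, d.hybrid_call) == (TRC, TRC, TRC)

    def test_discordant_resolves_to_pet(self):
        d = apply_thresholds({"tbr_max": 3.0, "rcbv": 2.0, "ktrans": 0.1})
        assert d.pet_call == POD
        assert d.mri_call == TRC
        assert d.discordant
        assert d.hybrid_call == POD

    def test_missing_metric_raises(self):
        with pytest.raises(ValueError, match="rcbv"):
            apply_thresholds({"tbr_max": 3.0, "ktrans": 0.1})


class TestHanleyCompare:
    labels = [POD] * 5 + [TRC] * 5

    def test_identical_scores_give_null(self):
        s = np.array([3.0, 2.5, 2.7, 1.9, 2.2, 1.5, 1.0, 2.0, 1.2, 0.9])
        cmp = hanley_compare(s, s, self.labels)
        assert cmp.z == 0.0
        assert cmp.p == 1.0

    def test_r_zero_reduces_to_unpaired(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10) + np.array([1.0] * 5 + [0.0] * 5)
        b = rng.normal(size=10)
        cmp = hanley_compare(a, b, self.labels, r=0.0)
        y = np.array([1] * 5 + [0] * 5)
        auc_a = mann_whitney_auc(a, y)
        auc_b = mann_whitney_auc(b, y)
        se_a = hanley_mcneil_se(auc_a, 5, 5)
        se_b = hanley_mcneil_se(auc_b, 5, 5)
        assert cmp.z == pytest.approx((auc_a - auc_b) / np.hypot(se_a, se_b))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hanley_compare([1.0, 2.0], [1.0], [POD, TRC])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_order_preserved(self):
        adj = benjamini_hochberg([0.04, 0.01, 0.02])
        assert adj == pytest.approx([0.04, 0.03, 0.03])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.data(),
    )
    def test_inflation_and_monotonicity(self, ps, data):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # elementwise-larger inputs never get smaller adjusted values
        bumps = data.draw(
            st.lists(
                st.floats(0.0, 0.5), min_size=len(ps), max_size=len(ps)
            )
        )
        larger = np.minimum(np.asarray(ps) + np.asarray(bumps), 1.0)
        assert np.all(benjamini_hochberg(larger) >= adj - 1e-12)


class TestConcordance:
    def test_all_concordant_all_correct(self):
        calls = [POD, TRC, POD]
        s = concordance_summary(calls, calls, calls)
        assert s.concordant_accuracy == 1.0
        assert s.n_discordant == 0
        assert s.pet_correct_when_discordant is None

    def test_swapping_modalities_swaps_discordant_fields(self):
        rng = np.random.default_rng(1)
        pet = np.where(rng.random(30) < 0.5, POD, TRC)
        mri = np.where(rng.random(30) < 0.5, POD, TRC)
        truth = np.where(rng.random(30) < 0.5, POD, TRC)
        a = concordance_summary(pet, mri, truth)
        b = concordance_summary(mri, pet, truth)
        assert a.n_concordant == b.n_concordant
        assert a.concordant_correct == b.concordant_correct
        assert a.pet_correct_when_discordant_n == b.mri_correct_when_discordant_n
        assert a.mri_correct_when_discordant_n == b.pet_correct_when_discordant_n

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            concordance_summary([POD], [POD, TRC], [POD, TRC])


class TestEstimators:
    def test_cutoff_classifier_fit_predict(self):
        from sklearn.base import clone

        scores = np.array([3.0, 2.8, 2.6, 1.2, 1.4, 1.1])
        labels = np.array([POD, POD, POD, TRC, TRC, TRC])
        clf = clone(CutoffClassifier(metric_name="tbr_max")).fit(scores, labels)
        assert clf.auc_ == 1.0
        assert list(clf.predict([3.5, 0.5])) == [POD, TRC]

    def test_threshold_rule_classifier(self):
        import pandas as pd

        frame = pd.DataFrame(
            [
                {"tbr_max": 2.75, "ktrans": 0.38, "rcbv": 3.0},
                {"tbr_max": 1.5, "ktrans": 0.1, "rcbv": 1.2},
            ]
        )
        clf = ThresholdRuleClassifier().fit()
        assert list(clf.predict(frame)) == [POD, TRC]
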