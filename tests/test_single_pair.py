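"""Single-pair classifier metrics: AUC, U-equivalence, logistic fit, gate."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import mirpair as m
from mirpair import stats
from mirpair.pairs import PairFeature


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: (wins + half-ties) / comparisons."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases, controls = scores[labels], scores[~labels]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (cases.size * controls.size)


def _feature(values):
    values = np.asarray(values, dtype=float)
    return PairFeature(
        mirna_a="miR-a",
        mirna_b="miR-b",
        delta_ct=values,
        any_censored=np.zeros(values.size, dtype=bool),
    )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = m.roc_auc([1, 2, 3, 4], [False, False, True, True])
        assert auc == 1.0
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        auc, _ = m.roc_auc([5, 5, 5, 5], [False, True, False, True])
        assert auc == 0.5

    def test_worked_example_against_pair_counting(self):
        scores = [3, 1, 2, 4]
        labels = [False, True, False, True]
        auc, _ = m.roc_auc(scores, labels)
        # 4 case-control comparisons: (1>3)F, (1>2)F, (4>3)T, (4>2)T
        assert auc == pytest.approx(2 / 4)
        assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            m.roc_auc([1, 2, 3], [True, True, True])

    @settings(max_examples=60, deadline=None)
    @given(
        scores=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=4, max_size=16
        ),
        case_count=st.integers(min_value=1, max_value=8),
    )
    def test_midrank_auc_matches_exhaustive_oracle(self, scores, case_count):
        """Rank-based AUC equals brute-force pair counting, ties included."""
        n = len(scores)
        case_count = min(case_count, n - 1)
        labels = np.array([True] * case_count + [False] * (n - case_count))
        assert stats.midrank_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        assert stats.midrank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestAucMwEquivalence:
    def test_tie_free_identity(self, rng):
        scores = rng.normal(size=10)
        labels = np.array([True] * 5 + [False] * 5)
        out = m.auc_equals_mw(scores, labels)
        assert abs(out["auc"] - out["u"] / 25.0) < 1e-12

    def test_perfect_separation_u(self):
        out = m.auc_equals_mw([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert out["u"] == 9.0
        assert out["auc"] == 1.0

    def test_all_equal_scores(self):
        out = m.auc_equals_mw([7.0] * 6, [False] * 3 + [True] * 3)
        assert out["u"] == pytest.approx(4.5)  # n1*n2/2
        assert out["auc"] == 0.5


class TestFitPairClassifier:
    def test_planted_shift_recovers_closed_form_auc(self):
        """Group shift 3 with unit assay noise: AUC ~= Phi(3 / sqrt(4))."""
        rng = np.random.default_rng(7)
        n = 30
        labels = np.array([True] * n + [False] * n)
        # delta-Ct feature of a pair: difference of two unit-variance assays
        case = rng.normal(3.0, np.sqrt(2.0), size=n)
        control = rng.normal(0.0, np.sqrt(2.0), size=n)
        result = m.fit_pair_classifier(_feature(np.concatenate([case, control])), labels)
        theoretical = norm.cdf(3.0 / np.sqrt(2.0 * 2.0))
        assert result.auc == pytest.approx(theoretical, abs=0.06)
        assert result.mw_p < 1e-6
        assert result.orientation == 1

    def test_constant_feature_degenerate(self):
        labels = np.array([True] * 5 + [False] * 5)
        result = m.fit_pair_classifier(_feature(np.zeros(10)), labels)
        assert result.degenerate
        assert result.auc == 0.5
        assert result.slope == 0.0
        # balanced cohorts: p = 0.5 everywhere, threshold rule calls case
        assert (result.sensitivity, result.specificity) in {(1.0, 0.0), (0.0, 1.0)}

    def test_label_permutation_centers_auc_at_half(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.normal(3.0, 1.0, 30), rng.normal(0.0, 1.0, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        aucs = []
        for _ in range(1000):
            perm = rng.permutation(60)
            aucs.append(stats.midrank_auc(values, labels[perm]))
        # raw (unoriented) AUC under permuted labels is symmetric around 0.5
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_perfect_separation_falls_back_to_step_rule(self):
        labels = np.array([False] * 4 + [True] * 4)
        result = m.fit_pair_classifier(_feature([1, 2, 3, 4, 10, 11, 12, 13]), labels)
        assert result.separable
        assert result.sensitivity == 1.0 and result.specificity == 1.0
        assert result.auc == 1.0

    def test_accuracy_identity_holds_for_screen(self, planted_results):
        for r in planted_results[::37]:
            expected = (r.sensitivity * r.n_case + r.specificity * r.n_control) / (
                r.n_case + r.n_control
            )
            assert r.accuracy == pytest.approx(expected, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, planted_cohort):
        ct, _, _, _ = planted_cohort
        feat = m.compute_pair_feature(ct, ct.assays[0], ct.assays[1])
        labels = ct.labels
        auc_log = stats.midrank_auc(feat.delta_ct, labels)
        auc_exp = stats.midrank_auc(np.exp2(feat.delta_ct), labels)
        assert auc_log == pytest.approx(auc_exp, abs=1e-12)

    def test_orientation_identity(self, planted_cohort):
        ct, _, _, _ = planted_cohort
        feat = m.compute_pair_feature(ct, ct.assays[0], ct.assays[1])
        labels = ct.labels
        forward = stats.midrank_auc(feat.delta_ct, labels)
        backward = stats.midrank_auc(feat.reversed().delta_ct, labels)
        assert forward == pytest.approx(1.0 - backward, abs=1e-12)


class TestConfidenceIntervals:
    def test_delong_degenerate_at_perfect_auc(self):
        labels = np.array([False] * 5 + [True] * 5)
        auc, lo, hi, degenerate = stats.delong_ci(np.arange(10.0), labels)
        assert auc == lo == hi == 1.0
        assert degenerate

    def test_delong_brackets_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1.0, 30), rng.normal(0.0, 1.0, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        auc, lo, hi, degenerate = stats.delong_ci(scores, labels)
        assert lo <= auc <= hi
        assert not degenerate
        assert 0.0 <= lo and hi <= 1.0

    def test_bootstrap_is_deterministic_given_seed(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1.0, 15), rng.normal(0.0, 1.0, 15)])
        labels = np.array([True] * 15 + [False] * 15)
        first = stats.bootstrap_auc_ci(scores, labels, seed=42, n_boot=200)
        second = stats.bootstrap_auc_ci(scores, labels, seed=42, n_boot=200)
        assert first == second

    def test_wider_level_gives_wider_interval(self, rng):
        scores = np.concatenate([rng.normal(1.0, 1.0, 30), rng.normal(0.0, 1.0, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        _, lo90, hi90, _ = stats.delong_ci(scores, labels, level=0.90)
        _, lo99, hi99, _ = stats.delong_ci(scores, labels, level=0.99)
        assert lo99 <= lo90 and hi90 <= hi99


class TestSelectPairs:
    def _result(self, pair_id, auc):
        return m.PairResult(
            pair_id=pair_id,
            mirna_a=pair_id.split("/")[0],
            mirna_b=pair_id.split("/")[1],
            orientation=1,
            intercept=0.0,
            slope=1.0,
            sensitivity=0.8,
            specificity=0.8,
            accuracy=0.8,
            auc=auc,
            auc_ci_low=auc - 0.05,
            auc_ci_high=min(auc + 0.05, 1.0),
            mw_u=450.0,
            mw_p=0.01,
            n_case=30,
            n_control=30,
        )

    def test_gate_is_inclusive_at_threshold(self):
        results = [
            self._result("miR-a/miR-b", 0.79),
            self._result("miR-a/miR-c", 0.80),
            self._result("miR-b/miR-c", 0.93),
        ]
        gated = m.select_pairs(results, auc_min=0.8)
        assert [r.pair_id for r in gated] == ["miR-b/miR-c", "miR-a/miR-c"]

    def test_all_below_gate_gives_empty_list(self):
        results = [self._result("miR-a/miR-b", 0.6), self._result("miR-a/miR-c", 0.7)]
        assert m.select_pairs(results, auc_min=0.8) == []

    def test_planted_pairs_all_pass_gate(self, planted_cohort, planted_results):
        """All five pairs planted at theoretical AUC 0.95 survive the 0.8 gate."""
        *_, pairs = planted_cohort
        gated_ids = {r.pair_id for r in m.select_pairs(planted_results, auc_min=0.8)}
        for a, b in pairs:
            assert f"{min(a, b)}/{max(a, b)}" in gated_ids

    def test_bh_column_present_but_not_gating(self, planted_results):
        table = m.results_table(planted_results[:50])
        assert "mw_p_bh" in table.columns
        assert (table["mw_p_bh"] >= table["mw_p"] - 1e-15).all()
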