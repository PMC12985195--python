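"""Equal-weight combination classifiers and the exhaustive search."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

import mirpair as m
from mirpair import stats
from mirpair.pairs import PairFeature, pair_feature_matrix


def _screen(ct):
    """Features dict + full screen results for a Ct matrix."""
    pairs, delta, cens = pair_feature_matrix(ct)
    feats = {
        f"{a}/{b}": PairFeature(mirna_a=a, mirna_b=b, delta_ct=delta[:, i], any_censored=cens[:, i])
        for i, (a, b) in enumerate(pairs)
    }
    return feats, m.evaluate_all_pairs(ct)


@pytest.fixture(scope="session")
def planted_screen(planted_cohort, planted_results):
    ct, *_ = planted_cohort
    pairs, delta, cens = pair_feature_matrix(ct)
    feats = {
        f"{a}/{b}": PairFeature(mirna_a=a, mirna_b=b, delta_ct=delta[:, i], any_censored=cens[:, i])
        for i, (a, b) in enumerate(pairs)
    }
    return ct, feats, planted_results


class TestBuildCombo:
    def test_k1_combo_matches_single_pair_auc(self, planted_screen):
        ct, feats, results = planted_screen
        best = m.select_pairs(results, auc_min=0.0)[0]
        combo = m.build_combo([best], feats, ct.labels)
        assert combo.auc == pytest.approx(best.auc, abs=1e-12)

    def test_identical_members_collapse_to_single_feature(self, planted_screen):
        ct, feats, results = planted_screen
        best = m.select_pairs(results, auc_min=0.0)[0]
        solo = m.build_combo([best], feats, ct.labels)
        with pytest.raises(ValueError, match="duplicate"):
            m.build_combo([best, best, best], feats, ct.labels)
        # the duplicate guard exists precisely because averaging identical
        # standardized features is a no-op:
        z = (feats[best.pair_id].delta_ct * best.orientation)
        triple_score = np.mean([z, z, z], axis=0)
        assert stats.midrank_auc(triple_score, ct.labels) == pytest.approx(solo.auc, abs=1e-12)

    def test_midpoint_sample_scores_zero_and_classifies_case(self):
        labels = np.array([True] * 3 + [False] * 3)
        # case mean 4, control mean 0; midpoint 2; last case sample sits on it
        values = np.array([4.0, 5.0, 2.0, 0.0, 1.0, -1.0])
        values = values - (values[labels].mean() + values[~labels].mean()) / 2.0 + 2.0
        feat = PairFeature("miR-a", "miR-b", values, np.zeros(6, dtype=bool))
        res = m.fit_pair_classifier(feat, labels)
        combo = m.build_combo([res], {res.pair_id: feat}, labels)
        midpoint = (combo.score[labels].mean() + combo.score[~labels].mean()) / 2.0
        assert midpoint == pytest.approx(0.0, abs=1e-12)
        on_boundary = np.isclose(combo.score, 0.0, atol=1e-12)
        assert np.all(combo.prob[on_boundary] == 0.5)
        # p >= 0.5 classifies as case, so boundary samples count toward sensitivity
        assert np.all(combo.prob[on_boundary] >= 0.5)

    def test_empty_member_list_errors(self, planted_screen):
        ct, feats, _ = planted_screen
        with pytest.raises(ValueError, match="at least one"):
            m.build_combo([], feats, ct.labels)

    def test_combining_independent_strong_pairs_beats_each_member(self):
        """Three independent planted pairs at theoretical AUC 0.9 combine
        to a higher empirical AUC than any single member."""
        d09 = 2.0 * 1.2815515655446004  # Phi(d / 2) = 0.9 at sigma = 1
        ids = [f"miR-x{i}" for i in range(6)]
        planted = {}
        for i in range(3):
            planted[ids[2 * i]] = +d09 / 2
            planted[ids[2 * i + 1]] = -d09 / 2
        cfg = m.SyntheticConfig(seed=5, n_assays=6, assay_ids=ids, planted=planted)
        ct, _, truth = m.generate_cohort(cfg)
        feats, results = _screen(ct)
        members = [
            r for r in m.select_pairs(results, auc_min=0.0)
            if tuple(sorted((r.mirna_a, r.mirna_b))) in {("miR-x0", "miR-x1"), ("miR-x2", "miR-x3"), ("miR-x4", "miR-x5")}
        ]
        assert len(members) == 3
        combo = m.build_combo(members, feats, ct.labels)
        assert combo.auc > max(r.auc for r in members)

    def test_anti_informative_member_drags_combo_down(self):
        """Equal weighting is not optimal: adding a pair whose feature is
        pure noise lowers the combo AUC below the best member's."""
        rng = np.random.default_rng(13)
        labels = np.array([True] * 30 + [False] * 30)
        strong = np.concatenate([rng.normal(4, 1, 30), rng.normal(0, 1, 30)])
        noise1 = rng.normal(0, 1, 60)  # uninformative members dilute the signal
        noise2 = rng.normal(0, 1, 60)
        feats = {}
        results = []
        for name, vals in (("miR-a/miR-b", strong), ("miR-c/miR-d", noise1), ("miR-e/miR-f", noise2)):
            a, b = name.split("/")
            f = PairFeature(a, b, vals, np.zeros(60, dtype=bool))
            feats[name] = f
            results.append(m.fit_pair_classifier(f, labels))
        best = max(results, key=lambda r: r.auc)
        combo = m.build_combo(results, feats, labels)
        assert combo.auc < best.auc

    def test_raw_ratio_mode_classifies_everything_as_case(self, planted_screen):
        """Regression guard documenting the literal printed formula: a mean
        of strictly positive ratios pushed through a sigmoid exceeds 0.5 for
        every sample, so specificity is exactly 0."""
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:3]
        combo = m.build_combo(gated, feats, ct.labels, mode="raw_ratio")
        assert combo.caveat
        assert np.all(combo.prob > 0.5)
        assert combo.sensitivity == 1.0
        assert combo.specificity == 0.0


class TestEvaluateCombo:
    def test_perfectly_separating_members(self):
        labels = np.array([True] * 5 + [False] * 5)
        vals = np.array([10.0] * 5 + [-10.0] * 5)
        feat = PairFeature("miR-a", "miR-b", vals, np.zeros(10, dtype=bool))
        res = m.fit_pair_classifier(feat, labels)
        combo = m.build_combo([res], {res.pair_id: feat}, labels)
        out = m.evaluate_combo(combo, labels)
        assert out == {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0, "auc": 1.0}

    def test_single_class_labels_error(self, planted_screen):
        ct, feats, results = planted_screen
        combo = m.build_combo(m.select_pairs(results, auc_min=0.8)[:2], feats, ct.labels)
        with pytest.raises(ValueError, match="single class"):
            m.evaluate_combo(combo, np.ones(ct.n_samples, dtype=bool))


class TestExhaustiveSearch:
    def test_three_gated_k3_gives_exactly_one_combination(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:3]
        ranked, n_eval = m.exhaustive_combo_search(gated, feats, ct.labels, k=3)
        assert n_eval == 1
        assert len(ranked) == 1

    def test_76_gate_evaluates_70300_combinations(self, planted_screen):
        ct, feats, results = planted_screen
        top76 = m.select_pairs(results, auc_min=0.0)[:76]
        ranked, n_eval = m.exhaustive_combo_search(top76, feats, ct.labels, k=3)
        assert n_eval == comb(76, 3) == 70300

    def test_top_combo_members_are_truly_differential(self, planted_screen, planted_cohort):
        """Truth-table recovery: the winning combination is built entirely
        from pairs the generator actually made differential."""
        ct, feats, results = planted_screen
        _, _, truth, _ = planted_cohort
        top76 = m.select_pairs(results, auc_min=0.0)[:76]
        ranked, _ = m.exhaustive_combo_search(top76, feats, ct.labels, k=3)
        differential = {
            f"{min(a, b)}/{max(a, b)}" for a, b in truth.differential_pairs()
        }
        assert all(mem in differential for mem in ranked.iloc[0]["members"])
        assert ranked.iloc[0]["auc"] >= max(r.auc for r in top76)

    def test_search_invariant_under_input_order(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:10]
        ranked_fwd, _ = m.exhaustive_combo_search(gated, feats, ct.labels, k=3)
        ranked_rev, _ = m.exhaustive_combo_search(gated[::-1], feats, ct.labels, k=3)
        assert ranked_fwd.drop(columns=["members"]).equals(ranked_rev.drop(columns=["members"]))

    def test_k1_search_reduces_to_single_pair_ranking(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:10]
        ranked, n_eval = m.exhaustive_combo_search(gated, feats, ct.labels, k=1)
        assert n_eval == 10
        single_order = [r.pair_id for r in sorted(gated, key=lambda r: (-r.auc, r.pair_id))]
        search_aucs = dict(zip(ranked["pair_1"], ranked["auc"]))
        for r in gated:
            assert search_aucs[r.pair_id] == pytest.approx(r.auc, abs=1e-12)
        assert list(ranked["auc"]) == sorted(ranked["auc"], reverse=True)
        assert ranked.iloc[0]["pair_1"] == single_order[0]

    def test_too_few_gated_errors(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:2]
        with pytest.raises(ValueError, match="at least k"):
            m.exhaustive_combo_search(gated, feats, ct.labels, k=3)

    def test_criteria_filter_applies(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:8]
        criteria = m.ComboCriteria(min_auc=0.99)
        ranked, n_eval = m.exhaustive_combo_search(gated, feats, ct.labels, k=3, criteria=criteria)
        assert n_eval == comb(8, 3)
        assert (ranked["auc"] >= 0.99).all() if len(ranked) else True

    def test_rerun_is_bit_identical(self, planted_screen):
        ct, feats, results = planted_screen
        gated = m.select_pairs(results, auc_min=0.8)[:8]
        r1, _ = m.exhaustive_combo_search(gated, feats, ct.labels, k=3)
        r2, _ = m.exhaustive_combo_search(gated, feats, ct.labels, k=3)
        assert r1.equals(r2)
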