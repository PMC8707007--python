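"""Discrimination and reclassification statistics against brute-force
and published-count oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskstrat import (ConfusionCounts, auroc, build_reclassification,
                       confusion_at_high, delong_compare, nri, sens_spec)
from riskstrat.metrics import ReclassificationTable


def _pair_count_auc(scores, events):
    """Brute-force concordant/discordant pair counting."""
    cases = [s for s, e in zip(scores, events) if e]
    ctrls = [s for s, e in zip(scores, events) if not e]
    total = wins = 0.0
    for c in cases:
        for d in ctrls:
            total += 1
            wins += 1.0 if c > d else (0.5 if c == d else 0.0)
    return wins / total


class TestConfusion:
    def test_published_t2d_rule_counts(self):
        """42,978 participants, 1,005 events, 14,169 advised of whom 819
        events -> tp 819, fn 186, fp 13,350, tn 28,623."""
        advised = np.zeros(42_978, dtype=bool)
        events = np.zeros(42_978, dtype=bool)
        advised[:14_169] = True
        events[:819] = True                 # advised events
        events[14_169:14_169 + 186] = True  # events among not-advised
        cc = confusion_at_high(advised, events)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (819, 186, 13_350, 28_623)
        assert cc.n == 42_978

    def test_all_advised_all_events(self):
        cc = confusion_at_high(np.ones(5, bool), np.ones(5, bool))
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (5, 0, 0, 0)

    def test_toy_vector_matches_hand_count(self):
        advised = np.array([1, 1, 0, 0, 1, 0], bool)
        events = np.array([1, 0, 1, 0, 1, 0], bool)
        cc = confusion_at_high(advised, events)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (2, 1, 1, 2)

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError):
            confusion_at_high(np.ones(3, bool), np.ones(4, bool))

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_cells_always_sum_to_cohort_size(self, pairs):
        advised = np.array([p[0] for p in pairs])
        events = np.array([p[1] for p in pairs])
        assert confusion_at_high(advised, events).n == len(pairs)


class TestSensSpec:
    def test_published_sensitivities(self):
        m = sens_spec(ConfusionCounts(tp=819, fn=186, fp=13_350, tn=28_623))
        assert 100 * m["sensitivity"].point == pytest.approx(81.5, abs=0.05)
        assert 100 * m["specificity"].point == pytest.approx(68.2, abs=0.05)
        m = sens_spec(ConfusionCounts(tp=360, fn=140, fp=0, tn=0))
        assert m["sensitivity"].point == pytest.approx(0.720)

    def test_zero_denominator_is_flagged_undefined(self):
        m = sens_spec(ConfusionCounts(tp=3, fn=2, fp=0, tn=0))
        assert np.isnan(m["specificity"].point)
        assert "undefined" in m["specificity"].method

    def test_zero_cells_can_be_floored_for_ratio_statistics(self):
        m = sens_spec(ConfusionCounts(tp=10, fn=0, fp=5, tn=20),
                      floor_zero_cells=True)
        assert m["sensitivity"].point == pytest.approx(10 / 11)

    def test_confidence_intervals_bracket_the_point(self):
        m = sens_spec(ConfusionCounts(tp=40, fn=10, fp=30, tn=120))
        for est in m.values():
            assert est.ci_low <= est.point <= est.ci_high
            assert 0.0 <= est.ci_low and est.ci_high <= 1.0


class TestAuroc:
    def test_perfect_separation_gives_one(self):
        scores = np.array([0, 0, 1, 1.0])
        events = np.array([0, 0, 1, 1], bool)
        assert auroc(scores, events, n_boot=0).point == 1.0

    def test_constant_scores_give_half(self):
        scores = np.zeros(10)
        events = np.array([0, 1] * 5, bool)
        assert auroc(scores, events, n_boot=0).point == 0.5

    def test_single_class_outcome_fails(self):
        with pytest.raises(ValueError):
            auroc(np.arange(4.0), np.ones(4, bool))

    def test_matches_pair_counting_exhaustively(self):
        """All score vectors over {0,1,2} and all event labellings, n<=5."""
        for n in (2, 3, 4, 5):
            for scores in itertools.product((0, 1, 2), repeat=n):
                for events in itertools.product((False, True), repeat=n):
                    if all(events) or not any(events):
                        continue
                    got = auroc(np.array(scores, float), np.array(events),
                                n_boot=0).point
                    assert got == pytest.approx(
                        _pair_count_auc(scores, events), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 4), st.booleans()),
                    min_size=2, max_size=12).filter(
        lambda ps: 0 < sum(p[1] for p in ps) < len(ps)))
    @settings(derandomize=True, max_examples=120)
    def test_matches_pair_counting_on_random_small_sets(self, pairs):
        scores = np.array([p[0] for p in pairs], float)
        events = np.array([p[1] for p in pairs])
        assert auroc(scores, events, n_boot=0).point == pytest.approx(
            _pair_count_auc(scores, events), abs=1e-12)

    def test_bootstrap_ci_brackets_point_and_is_seeded(self, rng):
        scores = rng.normal(size=200) + np.repeat([0, 1.0], 100)
        events = np.repeat([False, True], 100)
        a = auroc(scores, events, n_boot=200, seed=42)
        b = auroc(scores, events, n_boot=200, seed=42)
        assert a.ci_low <= a.point <= a.ci_high
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestDelong:
    def test_identical_predictors_give_zero_difference_p_one(self, rng):
        scores = rng.normal(size=40)
        events = rng.random(40) < 0.4
        est = delong_compare(scores, scores.copy(), events)
        assert est.point == 0.0
        assert est.p_value == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        events = np.repeat([False, True], 30)
        ab = delong_compare(a, b, events)
        ba = delong_compare(b, a, events)
        assert ab.point == pytest.approx(-ba.point)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_variance_agrees_with_paired_bootstrap(self, rng):
        """DeLong's analytic variance of the AUC difference should match a
        large paired bootstrap on a small dataset."""
        n = 40
        latent = rng.normal(size=n)
        events = latent + rng.normal(size=n) > 0.3
        a = latent + rng.normal(scale=0.8, size=n)
        b = latent + rng.normal(scale=1.2, size=n)
        est = delong_compare(a, b, events)

        boot_rng = np.random.default_rng(7)
        diffs = []
        for _ in range(4000):
            idx = boot_rng.integers(0, n, size=n)
            if events[idx].all() or not events[idx].any():
                continue
            diffs.append(auroc(a[idx], events[idx], n_boot=0).point
                         - auroc(b[idx], events[idx], n_boot=0).point)
        boot_se = np.std(diffs, ddof=1)
        assert est.se == pytest.approx(boot_se, rel=0.10)


class TestReclassification:
    def test_no_movement_when_classifiers_agree(self, rng):
        advised = rng.random(50) < 0.5
        events = rng.random(50) < 0.2
        tab = build_reclassification(advised, advised.copy(), events)
        assert tab.up_events == tab.down_events == 0
        assert tab.up_nonevents == tab.down_nonevents == 0

    def test_toy_crosstab_matches_hand_count(self):
        old = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0], bool)
        new = np.array([1, 0, 1, 1, 0, 0, 0, 1, 1, 0], bool)
        ev = np.array([1, 1, 0, 1, 1, 0, 0, 0, 1, 0], bool)
        tab = build_reclassification(old, new, ev)
        assert (tab.same_high_events, tab.down_events, tab.up_events,
                tab.same_low_events) == (2, 1, 1, 1)
        assert (tab.same_high_nonevents, tab.down_nonevents,
                tab.up_nonevents, tab.same_low_nonevents) == (1, 1, 1, 2)

    def test_published_hypertension_marginals(self):
        tab = ReclassificationTable(
            up_events=8, down_events=566, same_high_events=1751,
            same_low_events=54, up_nonevents=270, down_nonevents=13_793,
            same_high_nonevents=10_477, same_low_nonevents=6_622)
        assert tab.n_events == 2_379
        assert tab.n_events + tab.n_nonevents == 33_541


class TestNri:
    HTN = ReclassificationTable(8, 566, 1751, 54, 270, 13_793, 10_477, 6_622)
    T2D = ReclassificationTable(202, 109, 617, 77, 7_167, 5_725, 6_183, 22_898)

    def test_published_hypertension_value_and_interval(self):
        est = nri(self.HTN)
        assert est.point == pytest.approx(19.9, abs=0.05)
        assert est.ci_low == pytest.approx(18.1, abs=0.05)
        assert est.ci_high == pytest.approx(21.8, abs=0.05)
        assert est.p_value < 0.001

    def test_published_t2d_value_and_interval(self):
        est = nri(self.T2D)
        assert est.point == pytest.approx(5.8, abs=0.05)
        assert est.ci_low == pytest.approx(2.4, abs=0.05)
        assert est.ci_high == pytest.approx(9.3, abs=0.05)

    def test_identical_classifiers_give_zero(self):
        tab = ReclassificationTable(0, 0, 10, 20, 0, 0, 30, 40)
        assert nri(tab).point == 0.0

    def test_antisymmetric_under_classifier_swap(self):
        assert nri(self.HTN.swap()).point == pytest.approx(-nri(self.HTN).point)

    def test_requires_events_and_nonevents(self):
        with pytest.raises(ValueError):
            nri(ReclassificationTable(0, 0, 1, 1, 0, 0, 0, 0))

    def test_bootstrap_interval_agrees_with_asymptotic(self, rng):
        from riskstrat.metrics import nri_bootstrap
        old = rng.random(2000) < 0.5
        new = (old & (rng.random(2000) < 0.8)) | (rng.random(2000) < 0.15)
        events = rng.random(2000) < 0.25
        asym = nri(build_reclassification(old, new, events))
        boot = nri_bootstrap(old, new, events, n_boot=600, seed=5)
        assert boot.point == pytest.approx(asym.point)
        assert boot.se == pytest.approx(asym.se, rel=0.25)
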