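"""Threshold classifier, moment sweep and theta calls."""

import numpy as np
import pytest
from scipy import stats

from nanovario import (
    ParameterError,
    SampleRecord,
    accuracy,
    fit_threshold,
    moment_sweep,
    theta_call,
)


def records_from_sills(met, nonmet, unknown=(), q=1.0):
    recs = []
    for i, s in enumerate(met):
        recs.append(SampleRecord(f"m1.{i+1}", "metastatic", {q: s}))
    for i, s in enumerate(nonmet):
        recs.append(SampleRecord(f"nm1.{i+1}", "non_metastatic", {q: s}))
    for i, s in enumerate(unknown):
        recs.append(SampleRecord(f"u{i+1}", "unknown", {q: s}))
    return recs


class TestFitThreshold:
    def test_midpoint_threshold_and_rule(self):
        recs = records_from_sills([0.40, 0.50, 0.45], [0.70, 0.90], unknown=[0.60])
        res = fit_threshold(recs, 1.0)
        assert res.group_mean_met == pytest.approx(0.45)
        assert res.group_mean_nonmet == pytest.approx(0.80)
        assert res.threshold == pytest.approx(0.625)
        assert res.calls["u1"] == "metastatic"  # 0.60 below the line
        assert not res.inverted

    def test_perfect_separation_has_no_misclassification(self):
        recs = records_from_sills([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        res = fit_threshold(recs, 1.0)
        assert res.misclassified == []
        assert accuracy(res, recs) == (6, 6)

    def test_welch_p_value_against_t_distribution_oracle(self):
        # groups {1..5} and {2..6}: t = -1.0, Welch df = 8, p = 2*sf(1, 8)
        recs = records_from_sills([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        res = fit_threshold(recs, 1.0)
        assert abs(res.t_stat) == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 * stats.t.sf(1.0, 8), rel=1e-6)
        assert res.p_value == pytest.approx(0.347, abs=0.001)

    def test_threshold_strictly_between_distinct_group_means(self):
        res = fit_threshold(records_from_sills([0.2, 0.3], [0.5, 0.6]), 1.0)
        assert res.group_mean_met < res.threshold < res.group_mean_nonmet

    def test_scale_equivariance(self):
        recs = records_from_sills([0.2, 0.3, 0.25], [0.5, 0.6], unknown=[0.41])
        base = fit_threshold(recs, 1.0)
        k = 3.7
        scaled = records_from_sills(
            [k * 0.2, k * 0.3, k * 0.25], [k * 0.5, k * 0.6], unknown=[k * 0.41]
        )
        res = fit_threshold(scaled, 1.0)
        assert res.threshold == pytest.approx(k * base.threshold)
        assert res.calls == base.calls

    def test_tie_called_non_metastatic_and_flagged(self):
        recs = records_from_sills([0.2, 0.3], [0.5, 0.6], unknown=[0.40])
        res = fit_threshold(recs, 1.0)
        assert res.threshold == pytest.approx(0.40)
        assert res.calls["u1"] == "non_metastatic"
        assert "u1" in res.tied

    def test_inverted_orientation_flagged(self):
        res = fit_threshold(records_from_sills([0.8, 0.9], [0.1, 0.2]), 1.0)
        assert res.inverted

    def test_missing_class_or_too_few_raises(self):
        with pytest.raises(ParameterError):
            fit_threshold(records_from_sills([0.5, 0.6], [0.9]), 1.0)

    def test_zero_variance_both_groups_flags_p(self):
        res = fit_threshold(records_from_sills([0.2, 0.2], [0.5, 0.5]), 1.0)
        assert np.isnan(res.p_value)


class TestMomentSweep:
    @staticmethod
    def sweep_records(met, nonmet, unknown, q_list):
        recs = []
        for i, s in enumerate(met):
            recs.append(SampleRecord(f"m1.{i+1}", "metastatic", {q: s**q for q in q_list}))
        for i, s in enumerate(nonmet):
            recs.append(SampleRecord(f"nm1.{i+1}", "non_metastatic", {q: s**q for q in q_list}))
        for i, s in enumerate(unknown):
            recs.append(SampleRecord(f"u{i+1}", "unknown", {q: s**q for q in q_list}))
        return recs

    def test_rank_order_preserved_across_q(self):
        q_list = [0.5, 1.0, 3.0]
        recs = self.sweep_records([0.3, 0.4, 0.35], [0.8, 0.9, 0.85], [], q_list)
        for q in q_list:
            order = np.argsort([r.sills_by_q[q] for r in recs])
            base = np.argsort([r.sills_by_q[0.5] for r in recs])
            np.testing.assert_array_equal(order, base)

    def test_borderline_sample_changes_side_as_q_grows(self):
        # sill(1) = 0.95 sits above the q=1 midpoint threshold (0.825) but
        # below the q=5 one: the max-dominated group means shift the
        # midpoint past the sample as the moment grows
        q_list = [1.0, 5.0]
        recs = self.sweep_records([0.5, 0.6], [0.9, 1.3], [0.95], q_list)
        results = {r.q: r for r in moment_sweep(recs, q_list)}
        assert results[1.0].calls["u1"] == "non_metastatic"
        assert results[5.0].calls["u1"] == "metastatic"
        # direct computation of both sides
        thr1 = ((0.5 + 0.6) / 2 + (0.9 + 1.3) / 2) / 2
        thr5 = ((0.5**5 + 0.6**5) / 2 + (0.9**5 + 1.3**5) / 2) / 2
        assert 0.95 > thr1 and 0.95**5 < thr5

    def test_relative_separation_grows_with_q(self):
        q_list = [0.5, 1.0, 2.0, 5.0]
        recs = self.sweep_records([0.5, 0.6], [0.9, 1.0], [], q_list)
        seps = [r.separation_rel for r in moment_sweep(recs, q_list)]
        assert np.all(np.diff(seps) > 0)

    def test_bonferroni_scales_p(self):
        q_list = [0.5, 1.0]
        recs = self.sweep_records([0.3, 0.4, 0.35], [0.8, 0.9, 0.85], [], q_list)
        raw = moment_sweep(recs, q_list)
        adj = moment_sweep(recs, q_list, bonferroni=True)
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, 2 * r.p_value))


class TestThetaCall:
    def test_sign_rule(self):
        recs = [
            SampleRecord("m1.1", "metastatic", {1.0: 0.1}, theta_skewness=0.8),
            SampleRecord("nm1.1", "non_metastatic", {1.0: 0.5}, theta_skewness=-0.3),
        ]
        res = theta_call(recs)
        assert res.calls["m1.1"] == "metastatic"
        assert res.calls["nm1.1"] == "non_metastatic"
        assert res.agreement_rate == pytest.approx(1.0)

    def test_agreement_rate_by_hand_count(self):
        skews = [0.5, -0.2, 0.3, -0.4]  # calls: met, nonmet, met, nonmet
        labels = ["metastatic", "metastatic", "non_metastatic", "non_metastatic"]
        recs = [
            SampleRecord(f"s{i}", lab, {1.0: 0.1}, theta_skewness=sk)
            for i, (sk, lab) in enumerate(zip(skews, labels))
        ]
        # hand count: s0 correct, s1 wrong, s2 wrong, s3 correct -> 2/4
        assert theta_call(recs).agreement_rate == pytest.approx(0.5)

    def test_missing_skewness_raises(self):
        recs = [SampleRecord("s0", "metastatic", {1.0: 0.1})]
        with pytest.raises(ParameterError):
            theta_call(recs)
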