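"""Limits, recovery, precision, trueness and SRM comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sd_band
from halovalid.datamodel import SrmCertifiedValue
from halovalid.validate import (
    format_censored,
    limits_from_replicates,
    precision_inter,
    precision_intra,
    recovery,
    srm_compare,
    trueness,
)


class TestLimits:
    def test_zero_variance_gives_zero_limits(self):
        res = limits_from_replicates([0.1] * 10, 0.1)
        assert res.lod == 0.0 and res.loq == 0.0

    def test_limits_scale_with_replicate_sd(self):
        # ten values constructed to have sample SD exactly 0.0092
        vals = 0.1 + 0.0092 * np.array([-1, 1] * 5) * np.sqrt(9 / 10)
        assert np.std(vals, ddof=1) == pytest.approx(0.0092)
        res = limits_from_replicates(vals, 0.1)
        assert res.lod == pytest.approx(0.0276)
        assert res.loq == pytest.approx(0.092)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=6, max_size=20),
        st.floats(0.05, 1.0),
    )
    def test_loq_is_ten_thirds_of_lod(self, values, spike):
        res = limits_from_replicates(values, spike)
        assert res.loq == pytest.approx(res.lod * 10.0 / 3.0, rel=1e-12)

    def test_replicate_sd_within_sampling_band(self):
        """n = 10 determinations at 0.1 ug/kg with 9 % CV: the LOQ estimate
        must land inside the chi-square sampling band of 10 x SD."""
        rng = np.random.default_rng(42)
        sd_true = 0.1 * 0.09
        vals = 0.1 * (1 + rng.normal(0, 0.09, size=10))
        res = limits_from_replicates(vals, 0.1)
        lo, hi = sd_band(sd_true, 10)
        assert 10 * lo <= res.loq <= 10 * hi

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            limits_from_replicates([0.1], 0.1)

    def test_small_replicate_count_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            limits_from_replicates([0.1, 0.11, 0.09], 0.1)


class TestRecovery:
    def test_perfect_recovery(self):
        res = recovery([5.0, 5.0, 5.0], 5.0)
        assert res.recovery_pct == pytest.approx(100.0)
        assert res.rsd_pct == pytest.approx(0.0)
        assert res.acceptable

    def test_low_but_consistent_recovery_is_acceptable(self):
        res = recovery([0.57, 0.57, 0.57], 1.0)
        assert res.recovery_pct == pytest.approx(57.0)
        assert res.acceptable  # 30-140 % with RSD <= 20 %

    def test_recovery_above_140_is_unacceptable(self):
        assert not recovery([1.45, 1.45], 1.0).acceptable

    def test_inconsistent_recovery_is_unacceptable(self):
        res = recovery([0.3, 0.9], 0.6)
        assert res.rsd_pct > 20
        assert not res.acceptable

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError):
            recovery([1.0], 0.0)


class TestPrecision:
    def test_identical_values_have_zero_rsd(self):
        assert precision_intra([5.0] * 10) == pytest.approx(0.0)
        assert precision_inter([[5.0] * 4] * 4) == pytest.approx(0.0)

    def test_hand_computed_sample_rsd(self):
        # sample SD 0.2 around mean 5.0
        assert precision_intra([4.8, 5.0, 5.2]) == pytest.approx(4.0)

    def test_pooled_inter_day_equals_intra_on_pooled_values(self):
        days = [[4.8, 5.0], [5.2, 5.0]]
        pooled = [v for day in days for v in day]
        assert precision_inter(days) == pytest.approx(precision_intra(pooled))

    def test_pooled_rsd_reflects_between_plus_within_variance(self):
        """4 days x 4 replicates with 5 % between-day and 3 % within-day CV:
        total RSD estimates sqrt(25 + 9) ~ 5.83 %, within its sampling band."""
        rng = np.random.default_rng(7)
        days = [
            (5.0 * (1 + rng.normal(0, 0.05))
             * (1 + rng.normal(0, 0.03, size=4))).tolist()
            for _ in range(4)
        ]
        est = precision_inter(days)
        total_cv = np.sqrt(0.05**2 + 0.03**2) * 100
        # the between-day component carries only 3 degrees of freedom, so
        # the band is set by the day count, not the 16 pooled values
        lo, hi = sd_band(total_cv, 4)
        assert lo <= est <= hi

    def test_anova_estimator_recovers_structure(self):
        rng = np.random.default_rng(19)
        days = [
            (5.0 * (1 + rng.normal(0, 0.05))
             * (1 + rng.normal(0, 0.03, size=6))).tolist()
            for _ in range(8)
        ]
        est = precision_inter(days, method="anova")
        assert 3.0 <= est <= 9.0

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            precision_inter([[5.0, 5.1], []])


class TestTrueness:
    @pytest.mark.parametrize(
        "mean,ref,expected_rec",
        [(6.47, 7.25, 89), (5.0, 5.0, 100), (0.467, 0.742, 63)],
    )
    def test_recovery_matches_reference_comparisons(self, mean, ref, expected_rec):
        rec, bias = trueness(mean, ref)
        assert round(rec) == expected_rec
        assert bias == pytest.approx(rec - 100.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.001, 1e3), st.floats(0.001, 1e3))
    def test_recovery_minus_100_equals_bias(self, mean, ref):
        rec, bias = trueness(mean, ref)
        assert rec - 100.0 == pytest.approx(bias, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            trueness(1.0, 0.0)


class TestSrmCompare:
    def test_exact_agreement_is_in_range(self):
        cert = SrmCertifiedValue("x", 5.0, 0.5)
        res = srm_compare([5.0, 5.0, 5.0], cert)
        assert res.in_certified_range
        assert res.trueness_pct == pytest.approx(100.0)

    def test_low_result_falls_outside_tight_certified_interval(self):
        cert = SrmCertifiedValue("BDE-28", 0.742, 0.027)
        res = srm_compare([0.467, 0.467], cert)
        assert not res.in_certified_range
        assert round(res.trueness_pct) == 63

    def test_mean_check_vs_overlap_check(self):
        cert = SrmCertifiedValue("Lindane", 1.14, 0.18)
        assert not srm_compare([0.89, 0.89], cert).in_certified_range
        # with the determined expanded uncertainty the intervals overlap
        assert srm_compare(
            [0.89, 0.89], cert, determined_expanded_u=0.26
        ).in_certified_range


class TestCensoredReporting:
    def test_below_loq_reported_as_censored_string(self):
        assert format_censored(0.05, 0.092) == "<0.092"

    def test_quantifiable_value_reported_at_two_sig_figs(self):
        assert format_censored(0.2234, 0.092) == "0.22"
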