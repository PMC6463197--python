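"""Top-down uncertainty budget components and their combination."""

import csv
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sd_band
from halovalid.datamodel import QcSeries
from halovalid.uncertainty import (
    bias_components,
    build_budget,
    combine_budget,
    u_ref_for_analyte,
    u_ref_from_certificate,
    u_ref_from_purity,
    u_repro_from_qc,
)

# Published budget summary shipped with the package: the four components
# and the printed combined/expanded totals per analyte.
EXPECTED_TOTALS = {
    "Hexachloro-1,3-butadiene": (9.38, 18.8),
    "Pentachlorobenzene": (11.2, 22.4),
    "alpha-HCH": (13.2, 26.3),
    "Hexachlorobenzene": (11.2, 22.5),
    "beta-HCH": (14.2, 28.4),
    "Lindane": (14.4, 28.7),
    "delta-HCH": (11.9, 23.8),
    "Heptachlor": (10.2, 20.4),
    "BDE-28": (7.18, 14.4),
    "BDE-47": (8.36, 16.7),
    "BDE-100": (9.80, 19.6),
    "BDE-99": (8.32, 16.6),
    "BDE-154": (9.06, 18.1),
    "BDE-153": (10.9, 21.8),
}


def load_components():
    path = resources.files("halovalid").joinpath(
        "data/uncertainty_components.csv"
    )
    with path.open() as fh:
        return {
            row["analyte"]: (
                float(row["u_r_repro_pct"]),
                float(row["b_r_pct"]),
                float(row["u_r_cm_pct"]),
                float(row["u_r_ref_pct"]),
            )
            for row in csv.DictReader(fh)
        }


class TestReproducibility:
    def test_constant_chart_has_zero_reproducibility(self):
        series = QcSeries("x", 5.0, (5.0,) * 20)
        assert u_repro_from_qc(series) == 0.0

    def test_constructed_series_with_known_sd(self):
        # 20 values, mean 5.0, sample SD exactly 0.4 -> RSD 8.0 %
        offsets = 0.4 * np.array([-1, 1] * 10) * np.sqrt(19 / 20)
        series = QcSeries("x", 5.0, tuple(5.0 + offsets))
        assert u_repro_from_qc(series) == pytest.approx(8.0)

    def test_short_chart_warns(self):
        series = QcSeries("x", 5.0, tuple(np.linspace(4.5, 5.5, 12)))
        with pytest.warns(UserWarning, match="QC values"):
            u_repro_from_qc(series)


class TestBiasComponents:
    def test_unbiased_mean_gives_zero_bias(self):
        vals = [5.2, 4.8] * 5  # mean exactly 5.0
        b_r, _ = bias_components(vals, 5.0)
        assert b_r == pytest.approx(0.0)

    def test_standard_error_route(self):
        # nine values with sample SD exactly 0.3: u_cm = 0.1, u_r,cm = 2.0 %
        vals = [4.7] * 4 + [5.3] * 4 + [5.0]
        assert np.std(vals, ddof=1) == pytest.approx(0.3)
        with pytest.warns(UserWarning):
            b_r, u_r_cm = bias_components(vals, 5.0)
        assert u_r_cm == pytest.approx(2.0)

    def test_negative_bias_is_signed(self):
        vals = [0.87 * 5.0] * 10
        b_r, _ = bias_components(vals, 5.0)
        assert b_r == pytest.approx(-13.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            bias_components([5.0] * 10, 0.0)


class TestReferenceStandardUncertainty:
    @pytest.mark.parametrize("U,k,expected", [(2.0, 2, 1.0), (0.5, 2, 0.25), (0, 2, 0)])
    def test_certificate_route(self, U, k, expected):
        assert u_ref_from_certificate(U, k) == pytest.approx(expected)

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            u_ref_from_certificate(1.0, 0)

    @pytest.mark.parametrize(
        "purity,expected",
        [(100.0, 0.0), (96.0, 1.1547), (97.0, 0.866)],
    )
    def test_rectangular_distribution_route(self, purity, expected):
        assert u_ref_from_purity(purity) == pytest.approx(expected, abs=5e-4)

    def test_certificate_takes_precedence_over_purity(self, panel_map):
        # Hexachlorobenzene carries a certificate; its purity would give a
        # different (rectangular) value
        hcb = panel_map["Hexachlorobenzene"]
        assert u_ref_for_analyte(hcb) == pytest.approx(
            hcb.cert_expanded_u_pct / hcb.cert_coverage_k
        )
        # hexachloro-1,3-butadiene has no certificate: purity route
        hcbd = panel_map["Hexachloro-1,3-butadiene"]
        assert u_ref_for_analyte(hcbd) == pytest.approx(1.1547, abs=5e-4)


class TestCombination:
    def test_zero_components_combine_to_zero(self):
        assert combine_budget(0, 0, 0, 0) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "components,expected",
        [
            ((8.01, -4.66, 0.909, 1.15), (9.38, 18.8)),
            ((6.04, -13.0, 0.451, 0.866), (14.4, 28.7)),
        ],
    )
    def test_published_rows(self, components, expected):
        u_tot, U_tot = combine_budget(*components)
        assert u_tot == pytest.approx(expected[0], abs=0.05)
        assert U_tot == pytest.approx(expected[1], abs=0.1)

    def test_every_published_budget_row_reproduces(self):
        comps = load_components()
        assert set(comps) == set(EXPECTED_TOTALS)
        for analyte, (u_exp, U_exp) in EXPECTED_TOTALS.items():
            u_tot, U_tot = combine_budget(*comps[analyte])
            assert u_tot == pytest.approx(u_exp, abs=0.05), analyte
            assert U_tot == pytest.approx(U_exp, abs=0.1), analyte

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 20), st.floats(-20, 20), st.floats(0, 20), st.floats(0, 5)
    )
    def test_sign_symmetric_in_bias_and_expanded_is_double(self, u, b, cm, ref):
        u_tot_pos, U_pos = combine_budget(u, b, cm, ref)
        u_tot_neg, _ = combine_budget(u, -b, cm, ref)
        assert u_tot_pos == pytest.approx(u_tot_neg)
        assert U_pos == pytest.approx(2 * u_tot_pos)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(0, 20), st.floats(0, 20), st.floats(0, 20), st.floats(0, 5),
        st.floats(0.01, 5),
    )
    def test_monotone_in_component_magnitude(self, u, b, cm, ref, bump):
        base, _ = combine_budget(u, b, cm, ref)
        assert combine_budget(u + bump, b, cm, ref)[0] >= base
        assert combine_budget(u, b + bump, cm, ref)[0] >= base
        assert combine_budget(u, b, cm + bump, ref)[0] >= base
        assert combine_budget(u, b, cm, ref + bump)[0] >= base


class TestBudgetAssembly:
    def test_components_recovered_from_synthetic_qc_data(self, panel_map):
        """Injected CV 8 %, bias -5 %, purity 96 %: each estimated component
        must land in its analytic sampling band (n = 20 chart, n = 10 bias)."""
        rng = np.random.default_rng(5)
        hcbd = panel_map["Hexachloro-1,3-butadiene"]  # purity 96, no cert
        truth = 5.0 * 0.95
        chart = QcSeries(
            "Hexachloro-1,3-butadiene",
            5.0,
            tuple(truth * (1 + rng.normal(0, 0.08, size=20))),
        )
        bias_vals = truth * (1 + rng.normal(0, 0.08, size=10))
        budget = build_budget(hcbd, chart, bias_vals)

        lo, hi = sd_band(8.0, 20)
        assert lo * 0.95 <= budget.u_r_repro_pct <= hi  # RSD of biased mean
        se = 8.0 * 0.95 / np.sqrt(10)
        assert abs(budget.b_r_pct - (-5.0)) <= 1.96 * se
        assert budget.u_r_ref_pct == pytest.approx(1.1547, abs=5e-4)
        assert budget.U_r_tot_pct == pytest.approx(2 * budget.u_r_tot_pct)

    def test_mixed_reference_bases_rejected(self, panel_map):
        chart = QcSeries("Lindane", 5.0, (5.0,) * 20)
        with pytest.raises(ValueError, match="bases"):
            build_budget(panel_map["Lindane"], chart, [5.0] * 10, c_ref=4.0)
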