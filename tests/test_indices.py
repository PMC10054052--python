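"""Index formulas, classification schemes and their algebraic invariants."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mycorisk as m
from mycorisk import reference
from mycorisk.errors import DomainError

conc = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


class TestContaminationFactor:
    def test_background_soil_is_moderate_boundary(self, params):
        result = m.contamination_factor(0.06, params)
        assert result.value == pytest.approx(1.0)
        assert result.class_label == "moderate"  # boundary falls in upper class

    @pytest.mark.parametrize(
        "soil, expected, label",
        [
            (0.21, 3.5, "considerable"),
            (0.608, 10.13, "very_high"),
            (0.05, 0.833, "low"),
            (0.36, 6.0, "very_high"),
        ],
    )
    def test_published_and_boundary_values(self, params, soil, expected, label):
        result = m.contamination_factor(soil, params)
        assert result.value == pytest.approx(expected, rel=1e-2)
        assert result.class_label == label

    def test_nonpositive_soil_rejected(self, params):
        with pytest.raises(DomainError):
            m.contamination_factor(0.0, params)

    def test_reported_survey_values_split_3_9_2_2(self, params):
        cfis = [
            m.contamination_factor(value * params.background_hg, params)
            for value in reference.REPORTED_CFI.values()
        ]
        counts = m.classify_cfi_set(cfis)
        assert counts == {"low": 3, "moderate": 9, "considerable": 2, "very_high": 2}

    def test_classify_set_matches_per_value_binning(self, rng):
        values = rng.uniform(0.001, 12.0, size=1000)
        results = [m.contamination_factor(v * 0.06) for v in values]
        counts = m.classify_cfi_set(results)
        # independent per-value re-binning
        expected = {"low": 0, "moderate": 0, "considerable": 0, "very_high": 0}
        for v in values:
            if v < 1:
                expected["low"] += 1
            elif v < 3:
                expected["moderate"] += 1
            elif v < 6:
                expected["considerable"] += 1
            else:
                expected["very_high"] += 1
        assert counts == expected
        assert sum(counts.values()) == 1000

    def test_classify_set_empty_and_mixed(self):
        assert m.classify_cfi_set([]) == {
            "low": 0,
            "moderate": 0,
            "considerable": 0,
            "very_high": 0,
        }
        with pytest.raises(DomainError):
            m.classify_cfi_set([m.bioaccumulation_factor(1.0, 1.0)])


class TestRatioIndices:
    def test_bcf_boundary_value_is_excluder(self):
        result = m.bioaccumulation_factor(0.5, 0.5)
        assert result.value == 1.0 and result.class_label == "excluder"

    def test_bcf_accumulator_from_survey_means(self):
        # highest-contamination locality: cap mean 5.82 over soil mean 0.53
        result = m.bioaccumulation_factor(5.82, 0.53)
        assert result.value == pytest.approx(10.98, rel=1e-3)
        assert result.class_label == "accumulator"

    def test_bcf_small_ratio_is_excluder(self):
        assert m.bioaccumulation_factor(0.05, 0.5).class_label == "excluder"

    def test_translocation_identity_with_bcf(self, rng):
        for _ in range(100):
            cap, stem, soil = np.exp(rng.normal(size=3))
            qcs = m.translocation_quotient(cap, stem).value
            ratio = (
                m.bioaccumulation_factor(cap, soil).value
                / m.bioaccumulation_factor(stem, soil, part="stem").value
            )
            assert qcs == pytest.approx(ratio, rel=1e-14)

    def test_equal_cap_stem_gives_unity(self):
        assert m.translocation_quotient(0.7, 0.7).value == pytest.approx(1.0)


class TestDietaryIndices:
    def test_dw_fw_conversion_and_inverse(self, params):
        assert m.dw_to_fw(5.82, params) == pytest.approx(0.582)
        assert m.dw_to_fw(0.0, params) == 0.0
        assert m.dw_to_fw(1.23, params) / params.dry_matter_fraction == pytest.approx(1.23)

    @pytest.mark.parametrize(
        "conc_dw, expected",
        [(5.82, 37.4), (0.70, 4.50), (0.36, 2.31)],
    )
    def test_ptwi_published_values(self, params, conc_dw, expected):
        assert m.ptwi_percent(conc_dw, params).value == pytest.approx(expected, rel=5e-3)

    def test_ptwi_exactly_100_at_formula_pivot(self, params):
        pivot_dw = (params.ptwi_per_person / params.weekly_consumption_fw) / params.dry_matter_fraction
        result = m.ptwi_percent(pivot_dw, params)
        assert result.value == pytest.approx(100.0)
        assert result.class_label == "safe"  # hazard strictly above 100

    @pytest.mark.parametrize(
        "conc_dw, expected",
        [(5.82, 7.13), (1.89, 2.31), (0.97, 1.19), (0.41, 0.50), (0.70, 0.86)],
    )
    def test_thq_dw_published_values(self, params, conc_dw, expected):
        assert m.target_hazard_quotient(conc_dw, params, basis="DW").value == pytest.approx(
            expected, rel=1e-2
        )

    def test_thq_simplifies_when_at_equals_efr_times_ed(self, params):
        # Efr × ED = ATn under defaults, so THQ = ADC × CE × 1e-3 / (RfDo × BW)
        for ce in (0.01, 0.5, 3.3):
            expected = params.adc * ce * 1e-3 / (params.rfdo * params.body_weight)
            assert m.target_hazard_quotient(ce, params, basis="DW").value == pytest.approx(expected)

    def test_thq_basis_dw_fw_related_by_dry_matter_fraction(self, params):
        dw = m.target_hazard_quotient(2.0, params, basis="DW").value
        fw = m.target_hazard_quotient(2.0, params, basis="FW").value
        assert dw == pytest.approx(fw / params.dry_matter_fraction)
        with pytest.raises(DomainError):
            m.target_hazard_quotient(2.0, params, basis="WW")

    def test_ptwi_over_thq_fw_is_constant(self, params):
        """Under defaults %PTWI / THQ(FW) is the same constant for every
        concentration: both indices are linear in the FW concentration."""
        expected = (0.18 / 0.28 * 100) / (25.7e-3 / (0.0003 * 70))
        assert expected == pytest.approx(52.529, rel=1e-3)
        for conc in (0.01, 0.5, 5.82, 100.0):
            ratio = (
                m.ptwi_percent(conc, params).value
                / m.target_hazard_quotient(conc, params, basis="FW").value
            )
            assert ratio == pytest.approx(expected, rel=1e-12)


class TestProperties:
    @given(conc, st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_concentration(self, c, scale):
        params = m.ExposureParameters()
        for index in (
            lambda v: m.contamination_factor(v, params).value,
            lambda v: m.ptwi_percent(v, params).value,
            lambda v: m.target_hazard_quotient(v, params).value,
            lambda v: m.bioaccumulation_factor(v, 0.37).value,
            lambda v: m.translocation_quotient(v, 0.37).value,
        ):
            assert index(scale * c) == pytest.approx(scale * index(c), rel=1e-9)

    def test_indices_match_independent_arithmetic_on_random_parameters(self, rng):
        """Each index equals a plainly coded evaluation of its defining
        formula for 1000 random parameter sets."""
        for _ in range(1000):
            bg, ptwi_lim, wk, adc, rfdo, bw = np.exp(rng.normal(0, 1, size=6))
            efr = rng.uniform(100, 400)
            ed = rng.uniform(1, 80)
            atn = rng.uniform(100, 30000)
            dmf = rng.uniform(0.01, 1.0)
            c = float(np.exp(rng.normal()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = m.ExposureParameters(
                    background_hg=bg,
                    ptwi_per_person=ptwi_lim,
                    weekly_consumption_fw=wk,
                    adc=adc,
                    rfdo=rfdo,
                    body_weight=bw,
                    exposure_freq=efr,
                    exposure_duration=ed,
                    averaging_time=atn,
                    dry_matter_fraction=dmf,
                )
            assert m.contamination_factor(c, p).value == pytest.approx(c / bg, rel=1e-12)
            assert m.ptwi_percent(c, p).value == pytest.approx(
                (c * dmf) * wk / ptwi_lim * 100, rel=1e-12
            )
            assert m.target_hazard_quotient(c, p, basis="FW").value == pytest.approx(
                efr * ed * adc * (c * dmf) / (rfdo * bw * atn) * 1e-3, rel=1e-12
            )
            soil = float(np.exp(rng.normal()))
            assert m.bioaccumulation_factor(c, soil).value == pytest.approx(
                c / soil, rel=1e-12
            )
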