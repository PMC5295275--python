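"""Dose equation, exposure factor, unit-risk and mixture arithmetic."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ejdose import (
    DomainError,
    DoseParameters,
    RPFSet,
    UnitRisk,
    compute_add,
    compute_exposure_factor,
    compute_rpf,
    display_dose,
    format_dose,
    iced_mixture_dose,
    round_sig,
    scenario_dose_ratio,
    unit_risk_point_value,
)

positive = st.floats(min_value=1e-6, max_value=1e6)


def params(c=1.0, ir=1.0, ef=1.0, bw=1.0, k=1.0):
    return DoseParameters(
        concentration=c,
        intake_rate=ir,
        exposure_factor=ef,
        body_weight=bw,
        unit_conversion=k,
    )


class TestComputeAdd:
    @pytest.mark.parametrize(
        "c, ir, ef, bw, expected",
        [
            (5.0, 50.0, 0.125, 80.0, 3.90625e-4),  # affluent community, soil lead
            (5e3, 85.0, 1.0, 84.0, 5e3 * 85 / 84 * 1e-3),  # impacted community
            (0.0, 50.0, 1.0, 80.0, 0.0),
        ],
    )
    def test_examples(self, c, ir, ef, bw, expected):
        assert compute_add(params(c, ir, ef, bw, 1e-3)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_iff_a_factor_is_zero(self):
        assert compute_add(params(c=0)) == 0
        assert compute_add(params(ir=0)) == 0
        assert compute_add(params(ef=0)) == 0
        assert compute_add(params()) > 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bw": 0.0},
            {"bw": -5.0},
            {"c": -1.0},
            {"ir": -1.0},
            {"ef": -0.1},
            {"ef": 1.1},
            {"k": 0.0},
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(DomainError):
            params(**kwargs)

    @given(c=positive, ir=positive, ef=st.floats(1e-6, 1.0), bw=positive, s=positive)
    def test_homogeneity(self, c, ir, ef, bw, s):
        """ADD is linear in C, IR, EF and inversely linear in BW."""
        base = compute_add(params(c, ir, ef, bw))
        assert compute_add(params(c * s, ir, ef, bw)) == pytest.approx(base * s)
        assert compute_add(params(c, ir * s, ef, bw)) == pytest.approx(base * s)
        assert compute_add(params(c, ir, ef, bw * s)) == pytest.approx(base / s)


class TestExposureFactor:
    @pytest.mark.parametrize(
        "hours, expected", [(3.0, 0.125), (24.0, 1.0), (0.0, 0.0), (12.0, 0.5)]
    )
    def test_daily_fractions(self, hours, expected):
        assert compute_exposure_factor(hours) == expected

    def test_custom_averaging_time(self):
        assert compute_exposure_factor(1.0, averaging_hours=8.0) == 0.125

    def test_exceeding_averaging_time_rejected(self):
        with pytest.raises(DomainError):
            compute_exposure_factor(25.0)
        with pytest.raises(DomainError):
            compute_exposure_factor(-1.0)


class TestUnitRiskAndRpf:
    def test_range_midpoint(self):
        benzene = UnitRisk("benzene", (2.2e-6, 7.8e-6))
        assert unit_risk_point_value(benzene) == pytest.approx(5e-6)

    def test_scalar_passthrough_and_degenerate_range(self):
        assert unit_risk_point_value(UnitRisk("x", 3e-5)) == 3e-5
        assert unit_risk_point_value(UnitRisk("x", (3e-5, 3e-5))) == 3e-5

    def test_invalid_risks(self):
        with pytest.raises(DomainError):
            UnitRisk("x", 0.0)
        with pytest.raises(DomainError):
            UnitRisk("x", (7e-6, 2e-6))

    @pytest.mark.parametrize(
        "risk, index, expected",
        [(3e-5, 5e-6, 6.0), (2.2e-6, 5e-6, 0.44), (5e-6, 5e-6, 1.0)],
    )
    def test_rpf_examples(self, risk, index, expected):
        assert compute_rpf(risk, index) == pytest.approx(expected, rel=1e-12)

    def test_rpf_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            compute_rpf(0.0, 5e-6)
        with pytest.raises(DomainError):
            compute_rpf(3e-5, -1.0)

    @given(a=positive, b=positive)
    def test_rpf_reciprocal(self, a, b):
        assert compute_rpf(a, b) * compute_rpf(b, a) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rpfset_from_unit_risks_sets_index_to_exactly_one(self):
        rpfs = RPFSet.from_unit_risks(
            "benzene",
            {"benzene": (2.2e-6, 7.8e-6), "butadiene": 3e-5, "acetaldehyde": 2.2e-6},
        )
        assert rpfs.rpf["benzene"] == 1.0
        assert rpfs.rpf["butadiene"] == pytest.approx(6.0)
        assert rpfs.rpf["acetaldehyde"] == pytest.approx(0.44)

    def test_rpfset_invariants(self):
        with pytest.raises(DomainError):
            RPFSet("benzene", {"butadiene": 6.0})
        with pytest.raises(DomainError):
            RPFSet("benzene", {"benzene": 2.0})


class TestIcedMixture:
    def test_index_only_is_identity(self, benzene_rpfs):
        assert iced_mixture_dose({"benzene": 2e-4}, benzene_rpfs) == 2e-4

    def test_weighted_sum(self, benzene_rpfs):
        dose = iced_mixture_dose(
            {"benzene": 2e-4, "butadiene": 1e-5}, benzene_rpfs
        )
        assert dose == pytest.approx(2.6e-4, rel=1e-12)

    @given(
        b=st.floats(0, 1e-2),
        d=st.floats(0, 1e-2),
        a=st.floats(0, 1e-2),
    )
    def test_three_chemical_mixture_matches_termwise_sum(self, benzene_rpfs, b, d, a):
        """Cross-check against an explicitly written-out three-term sum."""
        expected = 1.0 * b + 6.0 * d + 0.44 * a
        got = iced_mixture_dose(
            {"benzene": b, "butadiene": d, "acetaldehyde": a}, benzene_rpfs
        )
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @given(
        doses=st.dictionaries(
            st.sampled_from(["benzene", "butadiene", "acetaldehyde"]),
            st.floats(0, 1e-2),
            min_size=1,
        )
    )
    def test_permutation_invariance_and_additivity(self, benzene_rpfs, doses):
        forward = iced_mixture_dose(doses, benzene_rpfs)
        reversed_order = dict(reversed(list(doses.items())))
        assert iced_mixture_dose(reversed_order, benzene_rpfs) == pytest.approx(
            forward, rel=1e-12, abs=1e-300
        )
        # additive over a disjoint split
        items = list(doses.items())
        left, right = dict(items[: len(items) // 2]), dict(items[len(items) // 2:])
        split_sum = sum(
            iced_mixture_dose(part, benzene_rpfs) for part in (left, right) if part
        )
        assert split_sum == pytest.approx(forward, rel=1e-12, abs=1e-300)
        weighted = [benzene_rpfs.rpf[c] * v for c, v in doses.items()]
        assert forward >= max(weighted) - 1e-300

    def test_missing_rpf_is_an_error(self, benzene_rpfs):
        with pytest.raises(DomainError, match="toluene"):
            iced_mixture_dose({"benzene": 1e-4, "toluene": 1e-4}, benzene_rpfs)


class TestRatioAndRounding:
    def test_ratio_of_displayed_doses(self):
        # ratio quoted from table-rounded doses
        assert scenario_dose_ratio(5.06, 3.91e-4) == pytest.approx(12941.18, abs=0.01)

    def test_full_precision_ratio_differs_from_quoted(self):
        full = scenario_dose_ratio(5e3 * 85 / 84 * 1e-3, 3.90625e-4)
        assert full == pytest.approx(12952.38, abs=0.01)

    def test_rounded_input_mode(self):
        got = scenario_dose_ratio(
            5e3 * 85 / 84 * 1e-3, 3.90625e-4, round_inputs_to_sig_figs=3
        )
        assert round(got) == 12941

    def test_identity_and_zero_denominator(self):
        assert scenario_dose_ratio(0.7, 0.7) == 1.0
        with pytest.raises(DomainError):
            scenario_dose_ratio(1.0, 0.0)

    @pytest.mark.parametrize(
        "x, sig, expected",
        [
            (3.90625e-4, 3, 3.91e-4),
            (5.0595238, 3, 5.06),
            (9.101941e-3, 3, 9.10e-3),
            (0.125, 2, 0.13),  # ties away from zero
            (-0.125, 2, -0.13),
            (0.0, 3, 0.0),
        ],
    )
    def test_round_sig(self, x, sig, expected):
        assert round_sig(x, sig) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "x, value, text",
        [
            (0.2253606, 0.23, "0.23"),
            (5.0595238, 5.06, "5.06"),
            (9.101941e-3, 9.10e-3, "9.10e-03"),
            (3.90625e-4, 3.91e-4, "3.91e-04"),
        ],
    )
    def test_display_convention(self, x, value, text):
        """Doses >= 0.01 print to two decimals, smaller ones to 3 sig figs."""
        assert display_dose(x) == pytest.approx(value, rel=1e-12)
        assert format_dose(x) == text
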