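"""Score binning, poverty fraction, and weighted-age computations."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ejdose import (
    AgeGroup,
    DomainError,
    ValidationError,
    assign_score,
    pooled_average_age,
    poverty_fraction,
    weighted_average_age,
)


class TestAssignScore:
    @pytest.mark.parametrize(
        "fraction, score",
        [(0.0, 1), (0.05, 1), (0.10, 2), (0.15, 2), (0.89, 9), (0.9, 10), (1.0, 10)],
    )
    def test_examples(self, fraction, score):
        assert assign_score(fraction) == score

    def test_rejects_out_of_range(self):
        for bad in (-0.01, 1.01, float("nan")):
            with pytest.raises(DomainError):
                assign_score(bad)

    def test_step_function_over_dense_grid(self):
        """Ten even half-open bins cover [0, 1]; scores are monotone 1..10."""
        previous = 1
        for k in range(0, 1001):
            f = k / 1000
            score = assign_score(f)
            # exact-rational oracle for the half-open binning rule
            frac = Fraction(k, 1000)
            expected = min(int(frac * 10) + 1, 10)
            assert score == expected
            assert 1 <= score <= 10
            assert score >= previous
            previous = score


class TestPovertyFraction:
    def test_examples(self):
        assert poverty_fraction([0.5, 1.0, 2.0, 3.0]) == 0.5
        assert poverty_fraction([1.5, 2.0, 10.0]) == 0.0
        # the threshold itself is not "below 1.5"
        assert poverty_fraction([1.5]) == 0.0
        assert poverty_fraction([1.4999]) == 1.0

    def test_empty_and_negative_rejected(self):
        with pytest.raises(DomainError):
            poverty_fraction([])
        with pytest.raises(DomainError):
            poverty_fraction([-0.1])

    @given(st.lists(st.floats(0, 5), min_size=1, max_size=30))
    def test_matches_bruteforce_count(self, ratios):
        count = 0
        for r in ratios:
            if r < 1.5:
                count += 1
        assert poverty_fraction(ratios) == count / len(ratios)


class TestWeightedAverageAge:
    def test_grouped_census_example(self):
        """10/20/40/30% across (0,10), (10,20), (20,60), 60+ with the
        open-ended group represented by age 90."""
        groups = [
            AgeGroup(0, 10, 0.10),
            AgeGroup(10, 20, 0.20),
            AgeGroup(20, 60, 0.40),
            AgeGroup(60, None, 0.30),
        ]
        expected = 5 * 0.10 + 15 * 0.20 + 40 * 0.40 + 90 * 0.30
        assert expected == 46.5
        assert weighted_average_age(groups, open_ended_value=90) == pytest.approx(46.5)

    def test_single_group_midpoint(self):
        assert weighted_average_age([AgeGroup(0, 10, 1.0)]) == 5.0

    def test_symmetric_groups_average_to_centre(self):
        groups = [AgeGroup(20, 30, 0.5), AgeGroup(30, 40, 0.5)]
        assert weighted_average_age(groups) == 30.0

    def test_order_invariance(self):
        groups = [
            AgeGroup(0, 10, 0.10),
            AgeGroup(10, 20, 0.20),
            AgeGroup(20, 60, 0.40),
            AgeGroup(60, None, 0.30),
        ]
        assert weighted_average_age(groups) == weighted_average_age(groups[::-1])

    def test_percent_sum_enforced(self):
        with pytest.raises(ValidationError):
            weighted_average_age([AgeGroup(0, 10, 0.4), AgeGroup(10, 20, 0.4)])

    @given(
        p=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        scale=st.floats(0.1, 3.0),
    )
    def test_linear_in_percent_vector(self, p, scale):
        """Scaling all percents (then renormalising) leaves the mean fixed;
        the raw weighted sum is linear in the percent vector."""
        total = sum(p)
        shares = [x / total for x in p]
        groups = [
            AgeGroup(10 * i, 10 * (i + 1), share) for i, share in enumerate(shares)
        ]
        mids = [g.midpoint(90) for g in groups]
        expected = sum(m * s for m, s in zip(mids, shares))
        assert weighted_average_age(groups) == pytest.approx(expected)

    def test_bounded_by_extreme_midpoints(self):
        groups = [
            AgeGroup(0, 10, 0.25),
            AgeGroup(10, 20, 0.25),
            AgeGroup(20, 60, 0.25),
            AgeGroup(60, None, 0.25),
        ]
        age = weighted_average_age(groups, open_ended_value=90)
        assert 5 <= age <= 90


class TestPooledAverageAge:
    def test_nested_means(self):
        assert pooled_average_age({"male": [40, 44], "female": [46, 50]}) == 45.0

    def test_constant_ages(self):
        assert pooled_average_age({"male": [37.2, 37.2], "female": [37.2]}) == 37.2

    def test_sex_then_tract_order_matters(self):
        # grand mean would be (40 + 50 + 50) / 3 = 46.67; nested mean is 45
        assert pooled_average_age({"male": [40], "female": [50, 50]}) == 45.0

    def test_dataframe_input(self):
        import pandas as pd

        df = pd.DataFrame(
            {"sex": ["male", "male", "female"], "age": [40.0, 44.0, 48.0]}
        )
        assert pooled_average_age(df) == 45.0

    def test_empty_sex_rejected(self):
        with pytest.raises(DomainError):
            pooled_average_age({"male": [], "female": [50]})
        with pytest.raises(DomainError):
            pooled_average_age({})
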