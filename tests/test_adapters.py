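"""Indicator adapters: diversity, endemic counts, key species, soil, WQ."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from safascore import (
    KeySpeciesWeights,
    Rating,
    SoilMeasurementSet,
    WQScoreSet,
    diversity_to_percent,
    endemic_count_to_rating,
    genetic_diversity_rating,
    key_species_score,
    shannon_index,
    soil_indicator_percent,
    wq_to_indicator_scores,
)

counts_strategy = st.lists(st.integers(min_value=1, max_value=10), min_size=1, max_size=5)


class TestShannonIndex:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10], 0.0),
            ([5, 5], math.log(2)),
            ([1, 1, 1, 1], math.log(4)),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", range(1, 8))
    def test_uniform_equals_log_richness(self, n):
        assert shannon_index([3] * n) == pytest.approx(math.log(n), abs=1e-12)

    @given(counts_strategy)
    def test_brute_force_oracle(self, counts):
        # independent direct summation of -p ln p
        total = sum(counts)
        expected = -sum((c / total) * math.log(c / total) for c in counts)
        assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    @given(counts_strategy, st.integers(min_value=2, max_value=7))
    def test_scale_invariance(self, counts, k):
        assert shannon_index([c * k for c in counts]) == pytest.approx(
            shannon_index(counts), abs=1e-9
        )

    @given(counts_strategy)
    def test_permutation_invariance(self, counts):
        assert shannon_index(list(reversed(counts))) == pytest.approx(
            shannon_index(counts), abs=1e-12
        )

    def test_zero_counts_omitted(self):
        assert shannon_index([5, 0, 5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_empty_or_all_zero_rejected(self):
        for bad in ([], [0, 0]):
            with pytest.raises(ValueError):
                shannon_index(bad)

    def test_bounded_by_log_richness(self):
        assert shannon_index([7, 2, 1]) <= math.log(3)


class TestDiversityToPercent:
    def test_cohort_maximum_gets_100(self):
        assert diversity_to_percent(1.2, 1.2) == pytest.approx(100.0)

    def test_zero_index(self):
        assert diversity_to_percent(0.0, 1.5) == 0.0

    def test_ratio(self):
        assert diversity_to_percent(math.log(2), math.log(4)) == pytest.approx(50.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            diversity_to_percent(0.5, 0.0)
        with pytest.raises(ValueError):
            diversity_to_percent(2.0, 1.0)


class TestGeneticDiversityRating:
    def test_two_farm_cohort(self, capture_table_factory):
        t_lo = capture_table_factory(
            "lo", [("birds", "a", 5, False, False, False), ("birds", "b", 5, False, False, False)]
        )
        t_hi = capture_table_factory(
            "hi", [("birds", f"s{i}", 1, False, False, False) for i in range(4)]
        )
        out = genetic_diversity_rating({"lo": t_lo, "hi": t_hi})
        assert out["hi"][0] == pytest.approx(100.0)
        assert out["hi"][1] is Rating.BEST
        assert out["lo"][0] == pytest.approx(50.0)

    def test_farm_with_no_captures_scores_zero(self, capture_table_factory):
        from safascore import CaptureTable

        t_hi = capture_table_factory(
            "hi", [("birds", "a", 2, False, False, False), ("birds", "b", 2, False, False, False)]
        )
        out = genetic_diversity_rating({"hi": t_hi, "none": CaptureTable.empty("none")})
        assert out["none"] == (0.0, Rating.UNACCEPTABLE)

    def test_absent_group_skipped(self, capture_table_factory, caplog):
        t = capture_table_factory(
            "f1", [("birds", "a", 3, False, False, False), ("birds", "b", 3, False, False, False)]
        )
        out = genetic_diversity_rating({"f1": t})  # bats/rodents absent everywhere
        assert out["f1"][0] == pytest.approx(100.0)


class TestEndemicCountRating:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (5, Rating.BEST),
            (4, Rating.GOOD),
            (3, Rating.MODERATE),
            (2, Rating.LIMITED),
            (1, Rating.UNACCEPTABLE),
            (0, Rating.UNACCEPTABLE),
            (7, Rating.BEST),  # clamped above the defined table
        ],
    )
    def test_table(self, n, expected):
        assert endemic_count_to_rating(n) is expected

    def test_monotone(self):
        ratings = [endemic_count_to_rating(n) for n in range(12)]
        assert all(b >= a for a, b in zip(ratings, ratings[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            endemic_count_to_rating(-1)


class TestKeySpeciesScore:
    def test_empty_table_scores_zero(self):
        from safascore import CaptureTable

        assert key_species_score(CaptureTable.empty("f")) == 0.0

    def test_maximal_configuration(self, capture_table_factory):
        t = capture_table_factory(
            "f",
            [("birds", "a", 1, True, True, False), ("bats", "b", 2, True, True, False)],
        )
        assert key_species_score(t) == pytest.approx(100.0)

    def test_default_weights_worked_example(self, capture_table_factory):
        # one endemic-only species (1 point), one introduced-only (floored to 0)
        # -> 100 * 1 / (2 species * 2 max points) = 25
        t = capture_table_factory(
            "f",
            [("birds", "a", 1, True, False, False), ("birds", "b", 1, False, False, True)],
        )
        assert key_species_score(t) == pytest.approx(25.0)

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=8,
        ),
        st.floats(min_value=0, max_value=3),
        st.floats(min_value=0, max_value=3),
        st.floats(min_value=0, max_value=3),
    )
    def test_bounded_for_any_weights(self, flags, we, wr, wi):
        from conftest import make_capture_table

        t = make_capture_table(
            "f",
            [
                ("birds", f"s{i}", 1, endemic, at_risk, introduced)
                for i, (endemic, at_risk, introduced) in enumerate(flags)
            ],
        )
        weights = KeySpeciesWeights(we, wr, wi, max_weight=max(we + wr, 1e-9))
        assert 0.0 <= key_species_score(t, weights) <= 100.0


class TestSoilIndicatorPercent:
    def _ms(self, ratios):
        props = {
            prop: (ref * ratios.get(prop, 1.0), ref, "u")
            for prop, ref in [
                ("texture_score", 100.0),
                ("organic_matter_pct", 6.0),
                ("no3_nh4_ratio", 8.0),
                ("total_organic_p", 500.0),
                ("total_organic_c", 45.0),
            ]
        }
        return SoilMeasurementSet("f", props)

    def test_measured_equal_reference_gives_100(self):
        ms = self._ms({})
        for indicator in (
            "soil-physical-structure",
            "soil-chemical-quality",
            "soil-biological-quality",
            "soil-organic-matter",
        ):
            assert soil_indicator_percent(ms, indicator) == pytest.approx(100.0)

    def test_single_property_ratio(self):
        ms = self._ms({"total_organic_c": 0.5})
        assert soil_indicator_percent(ms, "soil-organic-matter") == pytest.approx(50.0)

    def test_over_reference_capped(self):
        ms = self._ms({"total_organic_c": 1.5})
        assert soil_indicator_percent(ms, "soil-organic-matter") == pytest.approx(100.0)

    def test_two_property_mean(self):
        ms = self._ms({"no3_nh4_ratio": 0.4, "total_organic_p": 0.8})
        assert soil_indicator_percent(ms, "soil-chemical-quality") == pytest.approx(60.0)

    def test_missing_property_named_in_error(self):
        ms = SoilMeasurementSet("f", {"texture_score": (50.0, 100.0, "index")})
        with pytest.raises(ValueError, match="organic_matter_pct"):
            soil_indicator_percent(ms, "soil-physical-structure")

    @given(st.floats(min_value=0, max_value=5), st.floats(min_value=0, max_value=5))
    def test_bounded(self, r1, r2):
        ms = self._ms({"no3_nh4_ratio": r1, "total_organic_p": r2})
        assert 0.0 <= soil_indicator_percent(ms, "soil-chemical-quality") <= 100.0


class TestWQMapping:
    def test_principles_pass_through(self):
        wq = WQScoreSet(
            "f",
            {
                "good_feeding": 75.0,
                "good_health": 40.0,
                "appropriate_behavior": 90.0,
                "overall": 66.0,
            },
        )
        out = wq_to_indicator_scores(wq)
        assert out["animal-health-practices"] == 75.0
        assert out["animal-health"] == 40.0
        assert out["appropriate-animal-husbandry"] == 90.0
        assert out["freedom-of-stress"] == 66.0
        # no criterion scores -> handling falls back to overall
        assert out["humane-animal-handling-practices"] == 66.0

    def test_constant_input_propagates(self):
        wq = WQScoreSet(
            "f",
            {p: 50.0 for p in ("good_feeding", "good_health", "appropriate_behavior", "overall")},
        )
        assert set(wq_to_indicator_scores(wq).values()) == {50.0}

    def test_criterion_scores_averaged(self):
        wq = WQScoreSet(
            "f",
            {p: 80.0 for p in ("good_feeding", "good_health", "appropriate_behavior", "overall")},
            {"lameness": 60.0, "cleanliness": 80.0},
        )
        assert wq_to_indicator_scores(wq)["humane-animal-handling-practices"] == 70.0

    def test_missing_principle_names_blocked_indicator(self):
        wq = WQScoreSet("f", {"good_feeding": 75.0})
        with pytest.raises(ValueError, match="animal-health"):
            wq_to_indicator_scores(wq)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            WQScoreSet("f", {"good_feeding": 101.0})
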