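import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialnet.identity import canonicalize_authors
from trialnet.impact import (
    ImpactConfig,
    citation_score,
    cumulative_impact,
    manuscript_impact,
    role_coefficient,
    trial_coefficient,
    update_coefficient,
)

from conftest import make_record


class TestRoleCoefficient:
    @pytest.mark.parametrize(
        "position, n, equal, expected",
        [(1, 10, False, 3), (10, 10, False, 3), (5, 10, True, 3), (5, 10, False, 1), (1, 1, False, 3)],
    )
    def test_first_last_and_equal_contributors_score_three(self, position, n, equal, expected):
        assert role_coefficient(position, n, equal) == expected

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            role_coefficient(0, 5, False)
        with pytest.raises(ValueError):
            role_coefficient(6, 5, False)


class TestTrialCoefficient:
    @pytest.mark.parametrize("flags, expected", [([True], 2), ([False], 1), ([False, True], 2)])
    def test_any_randomized_trial_doubles(self, flags, expected):
        assert trial_coefficient(flags) == expected

    def test_empty_design_list_rejected(self):
        with pytest.raises(ValueError):
            trial_coefficient([])


class TestUpdateCoefficient:
    @pytest.mark.parametrize("index, expected", [(0, 1.0), (1, 0.5), (2, 0.25), (3, 0.125)])
    def test_half_life_decay_per_generation(self, index, expected):
        assert update_coefficient(index) == expected

    def test_pooled_updates_take_most_favourable_generation(self):
        assert update_coefficient(3, pooled_indices=[1, 3]) == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=1, max_size=5))
    def test_pooled_coefficient_equals_max_over_generations(self, pooled):
        direct = update_coefficient(0, pooled_indices=pooled)
        assert direct == max(0.5**i for i in pooled)

    def test_negative_indices_rejected(self):
        with pytest.raises(ValueError):
            update_coefficient(-1)
        with pytest.raises(ValueError):
            update_coefficient(0, pooled_indices=[-2])


class TestCitationScore:
    def test_maximum_cited_manuscript_scores_one(self):
        assert citation_score(13341, 13341, 2005) == 1.0

    def test_zero_citations_score_zero(self):
        assert citation_score(0, 13341, 1990) == 0.0

    def test_blend_adds_tier_median_at_full_weight(self):
        # end of the blend window: w = 1, so (100 + 200) / 1000 = 0.3
        got = citation_score(100, 1000, 2018, journal_tier=1, tier_median_table={1: 200.0})
        assert got == pytest.approx(0.3)

    def test_blend_weight_ramps_linearly(self):
        t = {1: 100.0}
        for year, w in [(2009, 0.1), (2013, 0.5), (2018, 1.0)]:
            got = citation_score(0, 1000, year, journal_tier=1, tier_median_table=t)
            assert got == pytest.approx(w * 100 / 1000)

    def test_missing_tier_median_inside_window_is_an_error(self):
        with pytest.raises(ValueError):
            citation_score(10, 100, 2015, journal_tier=2, tier_median_table={1: 5.0})

    def test_normalization_invariance_outside_blend_window(self):
        for k in (2, 10, 1000):
            assert citation_score(37 * k, 500 * k, 1999) == pytest.approx(citation_score(37, 500, 1999))


class TestManuscriptImpact:
    def test_first_author_randomized_primary_product(self):
        rec = make_record(authors=("A_Ann", "B_Bob", "C_Cyd"), citations=50, randomized=True)
        got = manuscript_impact(rec.authors[0], rec, max_citations=100)
        # 3 (first) x 2 (randomized) x 0.5 (citations) x 1 (primary) = 3.0
        assert got == {"breast": pytest.approx(3.0)}

    def test_middle_author_first_update_split_evenly(self):
        rec = make_record(
            authors=("A_Ann", "B_Bob", "C_Cyd"),
            citations=100,
            randomized=False,
            update_index=1,
            subspecialties={"A": 0.5, "B": 0.5},
        )
        got = manuscript_impact(rec.authors[1], rec, max_citations=100)
        # 1 x 1 x 1.0 x 0.5 split evenly across two subspecialties
        assert got == {"A": pytest.approx(0.25), "B": pytest.approx(0.25)}

    def test_zero_citation_score_zeroes_the_whole_map(self):
        rec = make_record(citations=0)
        got = manuscript_impact(rec.authors[1], rec, max_citations=100)
        assert all(v == 0.0 for v in got.values())

    def test_map_total_equals_scalar_score(self):
        rec = make_record(subspecialties={"A": 0.3, "B": 0.45, "C": 0.25}, citations=70)
        got = manuscript_impact(rec.authors[0], rec, max_citations=100)
        assert sum(got.values()) == pytest.approx(3 * 2 * 0.7)

    def test_coefficients_respond_to_config_scaling(self):
        rec = make_record(citations=100)
        cfg = ImpactConfig().scaled(role_factor=1.67, trial_factor=0.5)
        got = manuscript_impact(rec.authors[0], rec, max_citations=100, config=cfg)
        assert got["breast"] == pytest.approx(3 * 1.67 * 2 * 0.5)


class TestCumulativeImpact:
    def test_single_record_ledger_matches_contributions(self):
        rec = make_record(citations=100)
        key_map = canonicalize_authors([a.raw_name for a in rec.authors])
        ledger = cumulative_impact([rec], key_map)
        totals = ledger.total_by_author()
        assert totals["A_Ann"] == pytest.approx(6.0)  # first author
        assert totals["B_Bob"] == pytest.approx(2.0)  # middle
        assert totals["C_Cyd"] == pytest.approx(6.0)  # last

    def test_cutoff_before_first_record_gives_empty_ledger(self):
        rec = make_record(year=1990)
        key_map = canonicalize_authors([a.raw_name for a in rec.authors])
        ledger = cumulative_impact([rec], key_map, up_to_year=1980)
        assert ledger.total_by_author() == {}

    def test_cumulative_totals_never_decrease_over_years(self, tiny_corpus):
        records, truth = tiny_corpus
        key_map = canonicalize_authors([a.raw_name for r in records for a in r.authors])
        tiers = {int(k): v for k, v in truth["tier_median_table"].items()}
        ledger = cumulative_impact(records, key_map, None, tiers)
        years = sorted({r.year for r in records})
        prev: dict[str, float] = {}
        for y in years:
            cur = ledger.total_by_author(y)
            for a, v in prev.items():
                assert cur.get(a, 0.0) >= v - 1e-12
            prev = cur

    def test_author_score_is_independent_of_coauthors(self):
        solo = make_record(authors=("A_Ann", "Z_Zed"), citations=80)
        crowded = make_record(authors=("A_Ann", "B_Bob", "C_Cyd", "Z_Zed"), citations=80)
        s1 = manuscript_impact(solo.authors[0], solo, 100)
        s2 = manuscript_impact(crowded.authors[0], crowded, 100)
        assert s1 == s2
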