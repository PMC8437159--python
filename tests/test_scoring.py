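import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from dietshock.scoring import (
    ScoringOptions,
    classify_consumption_change,
    compute_dds,
    compute_pdqs,
    map_to_mddw_groups,
    map_to_pdqs_groups,
    score_household,
    score_records,
)
from dietshock.survey import FoodFrequencyRecord
from helpers import brute_dds, brute_pdqs


def random_days(codebook, rng):
    return {g: int(rng.integers(0, 8)) for g in codebook.survey_group_ids}


# -- mapping ---------------------------------------------------------------


def test_max_aggregator_takes_max(codebook, make_freq):
    # fish and poultry both feed meat/poultry/fish
    prof = map_to_mddw_groups(make_freq(fish=3, poultry=5), codebook, "max")
    assert prof.days_by_group["meat_poultry_fish"] == 5


def test_all_zero_maps_to_all_zero(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(days=0), codebook)
    assert all(v == 0 for g, v in prof.days_by_group.items() if g not in prof.excluded)


def test_sum_capped_aggregator_caps_at_seven(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(fish=4, poultry=5), codebook, "sum_capped")
    assert prof.days_by_group["meat_poultry_fish"] == 7


def test_missing_constituent_makes_group_missing(codebook, make_freq):
    freq = make_freq(fish=3)
    freq.days_by_group["poultry"] = None
    prof = map_to_mddw_groups(freq, codebook)
    assert prof.days_by_group["meat_poultry_fish"] is None


def test_maize_flour_products_count_as_refined_grains(codebook, make_freq):
    prof = map_to_pdqs_groups(make_freq(refined_grains=4), codebook)
    assert prof.servings_by_group["refined_grains"] == 4
    assert prof.healthy["refined_grains"] is False


def test_unknown_survey_group_raises(codebook):
    freq = FoodFrequencyRecord("during", {"mystery_meat": 3})
    with pytest.raises(KeyError):
        map_to_mddw_groups(freq, codebook)


# -- DDS -------------------------------------------------------------------


def test_dds_full_consumption_is_ten(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(days=7), codebook)
    assert compute_dds(prof).dds == 10


def test_dds_zero_consumption_is_zero(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(days=0), codebook)
    assert compute_dds(prof).dds == 0


def test_dds_six_of_seven_days_does_not_count(codebook, make_freq):
    # the daily-consumption rule: 6/7 < 1 per day
    prof = map_to_mddw_groups(make_freq(legumes=7, eggs=6), codebook)
    res = compute_dds(prof)
    assert res.dds == 1
    assert res.dds_contributions["legumes"] == 1
    assert res.dds_contributions["eggs"] == 0


def test_dds_relaxed_threshold_variant(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(legumes=7, eggs=6), codebook)
    assert compute_dds(prof, min_days=1).dds == 2


def test_dds_masked_group_contributes_zero(codebook, make_freq):
    prof = map_to_mddw_groups(make_freq(days=7), codebook)
    res = compute_dds(prof, mask=frozenset({"legumes"}))
    assert res.dds == 9
    assert res.dds_contributions["legumes"] == 0


# -- PDQS ------------------------------------------------------------------


def test_pdqs_zero_intake_is_twelve(codebook, make_freq):
    # forced by the point rules: 14 healthy x 0 + 6 unhealthy x 2
    prof = map_to_pdqs_groups(make_freq(days=0), codebook)
    assert compute_pdqs(prof).pdqs == 12


def test_pdqs_maximum_is_forty(codebook, make_freq):
    days = {g: 7 for g in codebook.healthy_ids}
    days |= {g: 0 for g in codebook.unhealthy_ids}
    prof = map_to_pdqs_groups(FoodFrequencyRecord("during", days), codebook)
    assert compute_pdqs(prof).pdqs == 40


def test_pdqs_all_twos_is_twenty(codebook, make_freq):
    prof = map_to_pdqs_groups(make_freq(days=2), codebook)
    assert compute_pdqs(prof).pdqs == 20


@pytest.mark.parametrize(
    "servings,healthy,expected",
    [(0, True, 0), (1, True, 0), (2, True, 1), (3, True, 1), (4, True, 2),
     (7, True, 2), (0, False, 2), (1, False, 2), (2, False, 1), (3, False, 1),
     (4, False, 0), (7, False, 0)],
)
def test_pdqs_point_bands(codebook, make_freq, servings, healthy, expected):
    gid = "legumes" if healthy else "red_meat"
    prof = map_to_pdqs_groups(make_freq(days=0, **{gid: servings}), codebook)
    assert compute_pdqs(prof).pdqs_points[gid] == expected


def test_pdqs_masked_group_contributes_zero(codebook, make_freq):
    prof = map_to_pdqs_groups(make_freq(days=0), codebook,
                              mask=frozenset({"red_meat"}))
    # zero intake normally scores 12; masking an unhealthy group removes its 2
    assert compute_pdqs(prof).pdqs == 10


# -- consumption change ----------------------------------------------------


@pytest.mark.parametrize(
    "before,during,expected",
    [(5, 3, "decreased"), (2, 2, "unchanged"), (0, 4, "increased")],
)
def test_classify_change(codebook, make_freq, before, during, expected):
    out = classify_consumption_change(
        make_freq("before", 0, legumes=before),
        make_freq("during", 0, legumes=during),
        "MDD-W",
        codebook,
    )
    assert out["legumes"] == expected


def test_classify_change_missing_is_indeterminate(codebook, make_freq):
    b = make_freq("before", 2)
    b.days_by_group["legumes"] = None
    out = classify_consumption_change(b, make_freq("during", 2), "MDD-W", codebook)
    assert out["legumes"] == "indeterminate"


def test_classify_change_pdqs_grouping(codebook, make_freq):
    out = classify_consumption_change(
        make_freq("before", 0, red_meat=4),
        make_freq("during", 0, red_meat=1),
        "PDQS",
        codebook,
    )
    assert out["red_meat"] == "decreased"
    assert len(out) == 20


# -- household/batch paths -------------------------------------------------


def test_site_mask_applied_per_household(codebook, make_record, make_freq):
    kersa = make_record(site="Kersa",
                        during=make_freq("during", 0,
                                         other_vitamin_a_fruits_vegetables=7))
    nouna = make_record(site="Nouna",
                        during=make_freq("during", 0,
                                         other_vitamin_a_fruits_vegetables=7))
    assert score_household(kersa, codebook)["during"].dds == 0
    assert score_household(nouna, codebook)["during"].dds == 1


def test_mask_disabled_by_option(codebook, make_record, make_freq):
    rec = make_record(site="Kersa",
                      during=make_freq("during", 0,
                                       other_vitamin_a_fruits_vegetables=7))
    opts = ScoringOptions(apply_site_masks=False)
    assert score_household(rec, codebook, opts)["during"].dds == 1


def test_completeness_flag(codebook, make_record):
    rec = make_record()
    rec.food_freq_during.days_by_group["eggs"] = None
    df = score_records([rec], codebook)
    assert bool(df.loc[0, "complete_before"]) is True
    assert bool(df.loc[0, "complete_during"]) is False


# -- invariants (property-based) -------------------------------------------

days_strategy = st.integers(min_value=0, max_value=7)


@settings(max_examples=150, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_score_ranges_and_integrality(codebook, data):
    days = {g: data.draw(days_strategy) for g in codebook.survey_group_ids}
    freq = FoodFrequencyRecord("during", days)
    dds = compute_dds(map_to_mddw_groups(freq, codebook)).dds
    pdqs = compute_pdqs(map_to_pdqs_groups(freq, codebook)).pdqs
    assert dds in range(0, 11)
    assert pdqs in range(0, 41)


@settings(max_examples=100, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_monotonicity_bump_never_hurts_dds(codebook, data):
    days = {g: data.draw(days_strategy) for g in codebook.survey_group_ids}
    gid = data.draw(st.sampled_from(codebook.survey_group_ids))
    freq = FoodFrequencyRecord("during", dict(days))
    base = compute_dds(map_to_mddw_groups(freq, codebook)).dds
    days[gid] = min(7, days[gid] + 1)
    bumped = compute_dds(
        map_to_mddw_groups(FoodFrequencyRecord("during", days), codebook)
    ).dds
    assert bumped >= base


@settings(max_examples=100, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_monotonicity_pdqs_healthy_up_unhealthy_down(codebook, data):
    days = {g: data.draw(days_strategy) for g in codebook.survey_group_ids}
    base = compute_pdqs(
        map_to_pdqs_groups(FoodFrequencyRecord("during", dict(days)), codebook)
    ).pdqs
    healthy_gid = data.draw(st.sampled_from(codebook.healthy_ids))
    up = dict(days)
    up[healthy_gid] = min(7, up[healthy_gid] + 1)
    up_score = compute_pdqs(
        map_to_pdqs_groups(FoodFrequencyRecord("during", up), codebook)
    ).pdqs
    assert up_score >= base
    unhealthy_gid = data.draw(st.sampled_from(codebook.unhealthy_ids))
    worse = dict(days)
    worse[unhealthy_gid] = min(7, worse[unhealthy_gid] + 1)
    worse_score = compute_pdqs(
        map_to_pdqs_groups(FoodFrequencyRecord("during", worse), codebook)
    ).pdqs
    assert worse_score <= base


@settings(max_examples=100, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_mask_monotonicity(codebook, data):
    days = {g: data.draw(days_strategy) for g in codebook.survey_group_ids}
    freq = FoodFrequencyRecord("during", days)
    gid = data.draw(st.sampled_from(codebook.survey_group_ids))
    base = compute_dds(map_to_mddw_groups(freq, codebook)).dds
    masked = compute_dds(
        map_to_mddw_groups(freq, codebook, mask=frozenset({gid}))
    ).dds
    assert masked <= base


@settings(max_examples=200, deadline=None,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(data=st.data())
def test_brute_force_agreement(codebook, data):
    days = {g: data.draw(days_strategy) for g in codebook.survey_group_ids}
    freq = FoodFrequencyRecord("during", days)
    for aggregator in ("max", "sum_capped"):
        prod = compute_dds(map_to_mddw_groups(freq, codebook, aggregator)).dds
        assert prod == brute_dds(days, codebook, aggregator=aggregator)
    prod_pdqs = compute_pdqs(map_to_pdqs_groups(freq, codebook)).pdqs
    assert prod_pdqs == brute_pdqs(days, codebook)


def test_brute_force_agreement_with_masks(codebook):
    rng = np.random.default_rng(7)
    for site in ("Kersa", "AddisAbaba"):
        mask = codebook.mask_for_site(site)
        for _ in range(200):
            days = random_days(codebook, rng)
            freq = FoodFrequencyRecord("during", days)
            prod = compute_dds(map_to_mddw_groups(freq, codebook, mask=mask)).dds
            assert prod == brute_dds(days, codebook, masked_survey_groups=mask)
            prod_p = compute_pdqs(map_to_pdqs_groups(freq, codebook, mask=mask)).pdqs
            assert prod_p == brute_pdqs(days, codebook, masked_survey_groups=mask)


def test_invalid_options_rejected():
    with pytest.raises(ValueError):
        ScoringOptions(aggregator="mean")
    with pytest.raises(ValueError):
        ScoringOptions(dds_min_days=0)
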