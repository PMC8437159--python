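import numpy as np
import pytest

from dietshock._util import round_half_up
from dietshock.descriptives import (
    characteristics_table,
    consumption_change_summary,
    mean_scores_before_during,
    price_change_table,
)
from dietshock.scoring import classify_consumption_change
from helpers import brute_dds, brute_pdqs


def test_round_half_up_ties():
    assert round_half_up(90.05) == 90.1
    assert round_half_up(69.59707, 1) == 69.6
    assert round_half_up(2.25, 1) == 2.3  # not banker's rounding


def _price_records(make_record, site, unchanged, decreased, increased, cat="staples"):
    recs = []
    i = 0
    for level, n in (("unchanged", unchanged), ("decreased", decreased),
                     ("increased", increased)):
        for _ in range(n):
            r = make_record(household_id=f"{site}-{i}", site=site)
            r.price_changes = dict(r.price_changes)
            r.price_changes[cat] = level
            recs.append(r)
            i += 1
    return recs


def test_overall_staples_percentage(make_record):
    # counts 144 / 24 / 1533 -> increased 90.1% of the 1701 non-missing
    recs = _price_records(make_record, "Nouna", 144, 24, 1533)
    table = price_change_table(recs)
    cell = table.cell("price_staples", "increased", "Overall")
    assert cell["count"] == 1533
    assert cell["denominator"] == 1701
    assert cell["percentage"] == 90.1


def test_site_staples_percentage(make_record):
    recs = _price_records(make_record, "Lagos", 3, 1, 299)
    assert price_change_table(recs).percentage(
        "price_staples", "increased", "Lagos"
    ) == 98.7


def test_missing_responses_excluded_from_denominator(make_record):
    recs = _price_records(make_record, "Nouna", 2, 0, 6)
    for r in recs[:2]:
        r.price_changes["staples"] = None
    table = price_change_table(recs)
    cell = table.cell("price_staples", "increased", "Nouna")
    assert cell["denominator"] == 6
    missing = table.cell("price_staples", "missing", "Nouna")
    assert missing["count"] == 2


def test_all_missing_site_reports_zero_denominator(make_record):
    recs = _price_records(make_record, "Kersa", 0, 0, 4)
    for r in recs:
        r.price_changes["staples"] = None
    cell = price_change_table(recs).cell("price_staples", "increased", "Kersa")
    assert cell["denominator"] == 0
    assert np.isnan(cell["percentage"])


def test_food_security_rows(make_record):
    recs = [make_record(household_id=str(i), site="Kersa", worried_food=i < 236)
            for i in range(297)]
    assert price_change_table(recs).percentage("worried_food", True, "Kersa") == 79.5


# -- characteristics -------------------------------------------------------


def test_female_percentage(make_record):
    recs = [
        make_record(household_id=str(i),
                    respondent_sex="female" if i < 658 else "male")
        for i in range(1797)
    ]
    freq, _ = characteristics_table(recs)
    assert freq.percentage("respondent_sex", "female", "Overall") == 36.6


def test_single_record_is_hundred_percent(make_record):
    freq, cont = characteristics_table([make_record(respondent_sex="female")])
    assert freq.percentage("respondent_sex", "female", "Overall") == 100.0
    assert cont.loc[cont.stratum == "Overall", "mean"].iloc[0] == 5.0


def test_all_sex_missing_zero_denominator(make_record):
    recs = [make_record(household_id=str(i), respondent_sex=None) for i in range(4)]
    freq, _ = characteristics_table(recs)
    cell = freq.cell("respondent_sex", "female", "Overall")
    assert cell["denominator"] == 0 and np.isnan(cell["percentage"])


def test_household_size_mean_sd(make_record):
    sizes = [2, 4, 6, 8]
    recs = [make_record(household_id=str(i), household_size=s)
            for i, s in enumerate(sizes)]
    _, cont = characteristics_table(recs)
    row = cont[cont.stratum == "Overall"].iloc[0]
    assert row["mean"] == pytest.approx(np.mean(sizes))
    assert row["sd"] == pytest.approx(np.std(sizes, ddof=1))


def test_counts_plus_missing_equal_n(make_record):
    recs = [make_record(household_id=str(i),
                        education=None if i % 3 == 0 else "secondary_or_higher")
            for i in range(9)]
    freq, _ = characteristics_table(recs)
    d = freq.data
    sub = d[(d.variable == "education") & (d.stratum == "Overall")]
    cat_total = sub[sub.category != "missing"]["count"].sum()
    missing = sub[sub.category == "missing"]["count"].iloc[0]
    assert cat_total + missing == 9


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        characteristics_table([])


# -- consumption change ----------------------------------------------------


def test_all_decreased(make_record):
    recs = [make_record(household_id=str(i), days_before=5, days_during=2)
            for i in range(6)]
    cs = consumption_change_summary(recs, "MDD-W")
    cell = cs.cell("legumes", "Overall")
    assert cell["pct_decreased"] == 100.0


def test_all_unchanged(make_record):
    recs = [make_record(household_id=str(i), days_before=3, days_during=3)
            for i in range(6)]
    cell = consumption_change_summary(recs, "MDD-W").cell("eggs", "Overall")
    assert cell["pct_unchanged"] == 100.0
    assert cell["pct_decreased"] == 0.0


def test_mixed_set_matches_hand_tally(codebook, make_record, make_freq):
    # 20 records with known before/during legume days; brute tally in-test
    rng = np.random.default_rng(0)
    recs, statuses = [], []
    for i in range(20):
        b, d = int(rng.integers(0, 8)), int(rng.integers(0, 8))
        recs.append(
            make_record(household_id=str(i),
                        before=make_freq("before", 0, legumes=b),
                        during=make_freq("during", 0, legumes=d))
        )
        statuses.append("decreased" if d < b else "increased" if d > b else "unchanged")
    cs = consumption_change_summary(recs, "MDD-W")
    cell = cs.cell("legumes", "Overall")
    for status in ("decreased", "unchanged", "increased"):
        expected = 100.0 * statuses.count(status) / 20
        assert cell[f"pct_{status}"] == round_half_up(expected)


def test_percentages_sum_to_hundred(make_record):
    recs = [make_record(household_id=str(i), days_before=i % 8, days_during=(i * 3) % 8)
            for i in range(40)]
    cs = consumption_change_summary(recs, "MDD-W")
    for _, row in cs.data.iterrows():
        if row["n"]:
            total = row["pct_decreased"] + row["pct_unchanged"] + row["pct_increased"]
            assert total == pytest.approx(100.0, abs=0.15)  # within rounding


# -- score summaries -------------------------------------------------------


def test_identical_periods_identical_summaries(make_record):
    recs = [make_record(household_id=str(i), days_before=4, days_during=4)
            for i in range(8)]
    df = mean_scores_before_during(recs)
    overall = df[df.stratum == "Overall"].set_index("period")
    assert overall.loc["before", "dds_mean"] == overall.loc["during", "dds_mean"]
    assert overall.loc["before", "pdqs_median"] == overall.loc["during", "pdqs_median"]


def test_constant_dds_two(make_record, make_freq):
    # legumes and eggs daily -> DDS exactly 2 at an unmasked site
    recs = [
        make_record(household_id=str(i), site="Nouna",
                    during=make_freq("during", 0, legumes=7, eggs=7))
        for i in range(5)
    ]
    df = mean_scores_before_during(recs)
    row = df[(df.stratum == "Nouna") & (df.period == "during")].iloc[0]
    assert row["dds_mean"] == 2.0
    assert row["dds_sd"] == 0.0


def test_pdqs_median_iqr_match_hand_calculation(codebook, make_record, make_freq):
    rng = np.random.default_rng(3)
    recs, brute_vals = [], []
    for i in range(5):
        days = {g: int(rng.integers(0, 8)) for g in codebook.survey_group_ids}
        recs.append(
            make_record(household_id=str(i), site="Ouagadougou",
                        during=make_freq("during", 0, **days))
        )
        brute_vals.append(brute_pdqs(days, codebook))
    df = mean_scores_before_during(recs)
    row = df[(df.stratum == "Ouagadougou") & (df.period == "during")].iloc[0]
    assert row["pdqs_median"] == np.median(brute_vals)
    assert row["pdqs_q1"] == np.percentile(brute_vals, 25)
    assert row["pdqs_q3"] == np.percentile(brute_vals, 75)


def test_incomplete_records_excluded_per_period(make_record):
    recs = [make_record(household_id=str(i), days_before=2, days_during=2)
            for i in range(4)]
    recs[0].food_freq_during.days_by_group["fish"] = None
    df = mean_scores_before_during(recs)
    overall = df[df.stratum == "Overall"].set_index("period")
    assert overall.loc["before", "n"] == 4
    assert overall.loc["during", "n"] == 3
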