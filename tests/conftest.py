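import pytest

from dietshock.codebook import load_codebook
from dietshock.survey import (
    FoodFrequencyRecord,
    HouseholdRecord,
    PRICE_CATEGORIES,
    SITES,
)


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


@pytest.fixture
def make_freq(codebook):
    def _make(period="during", days=0, **per_group):
        base = {g: days for g in codebook.survey_group_ids}
        for gid, d in per_group.items():
            assert gid in base, gid
            base[gid] = d
        return FoodFrequencyRecord(period, base)

    return _make


@pytest.fixture
def make_record(codebook, make_freq):
    """Factory for a valid household record with sensible defaults."""

    def _make(site="Nouna", days_before=0, days_during=0, before=None,
              during=None, **overrides):
        country, locality = SITES[site]
        rec = HouseholdRecord(
            household_id=overrides.pop("household_id", "h1"),
            country=country,
            site=site,
            locality=locality,
            respondent_sex="male",
            age_band="30-39",
            education="primary_or_incomplete_secondary",
            head_of_household=True,
            household_size=5,
            occupation="employed",
            price_changes={c: "increased" for c in PRICE_CATEGORIES},
            worried_food=False,
            skipped_meal=False,
            whole_day_no_food=False,
            social_assistance=False,
            assistance_type=None,
            crop_production="unchanged",
            food_freq_before=before or make_freq("before", days_before),
            food_freq_during=during or make_freq("during", days_during),
        )
        for key, value in overrides.items():
            if not hasattr(rec, key):
                raise AttributeError(key)
            setattr(rec, key, value)
        return rec

    return _make
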