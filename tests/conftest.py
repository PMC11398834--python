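import pandas as pd
import pytest
from hypothesis import settings

import tnfvigil as tv

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


def make_reports(rows):
    """Build a cleaned-report frame from (case_id, version, sex, ps_drug,
    events, indications, reporter) tuples with sensible defaults."""
    defaults = dict(
        version=1,
        sex="female",
        age_years=50.0,
        weight_kg=70.0,
        country="US",
        reporter="physician",
        ps_drug="adalimumab",
        events=("arthralgia",),
        outcomes=(),
        indications=("rheumatoid arthritis",),
        therapy_start=pd.NaT,
        event_date=pd.NaT,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, case_id=str(i))
        rec.update(row)
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["therapy_start"] = pd.to_datetime(df["therapy_start"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return tv.time_to_onset(df)


@pytest.fixture(scope="session")
def small_scenario():
    return tv.default_scenario(n_reports=5000, seed=11)


@pytest.fixture(scope="session")
def small_raw(small_scenario):
    return tv.generate(small_scenario)


@pytest.fixture(scope="session")
def small_reports(small_raw):
    return tv.deduplicate(tv.assemble_reports(small_raw))


@pytest.fixture(scope="session")
def small_filtered(small_reports):
    return tv.apply_inclusion_filters(small_reports)
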