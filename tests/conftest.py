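import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragix import CorpusTable, TrialRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20220509)


def make_record(i: int, events_int: int, n_int: int, events_ctl: int, n_ctl: int,
                **overrides) -> TrialRecord:
    base = dict(
        trial_id=f"T{i:03d}",
        first_author=f"Author{i}",
        year=2015,
        journal="Other Journal",
        multicenter="yes",
        double_blinded="no",
        registered="yes",
        itt=True,
        outcome_used="primary",
        n_int=n_int,
        n_ctl=n_ctl,
        events_int=events_int,
        events_ctl=events_ctl,
        n_lost_followup=0,
        reported_p=None,
    )
    base.update(overrides)
    return TrialRecord(**base)


@pytest.fixture
def small_corpus() -> CorpusTable:
    """Six significant 1:1 trials with varied metadata, plus distinct
    journals/years, suitable for subgroup and correlation smoke tests."""
    records = [
        make_record(1, 0, 20, 10, 20, year=1995,
                    journal="New England Journal of Medicine", reported_p=0.001),
        make_record(2, 2, 30, 12, 30, year=2005, journal="Journal of Pediatrics",
                    multicenter="no", itt=False, reported_p=0.004),
        make_record(3, 5, 50, 20, 50, year=2010, journal="Neonatology",
                    double_blinded="yes", n_lost_followup=8, reported_p=0.002),
        make_record(4, 3, 40, 15, 40, year=2012, journal="Pediatrics",
                    registered="no", outcome_used="secondary", reported_p=0.003),
        make_record(5, 10, 100, 30, 100, year=2018, journal="JAMA",
                    n_lost_followup=12, reported_p=0.001),
        make_record(6, 1, 25, 9, 25, year=2020, journal="The Lancet",
                    multicenter="unsure", itt=False, reported_p=0.01),
    ]
    return CorpusTable(records=records, provenance="fixture")
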