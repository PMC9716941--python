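import numpy as np
import pytest

from pulvalid import (Cohort, PULRecord, default_params, generate_cohort,
                      load_builtin)


def make_record(id="r1", hcg1=500.0, hcg2=500.0, interval=48.0, outcome="failed_pul",
                **kw):
    return PULRecord(id=id, age=30.0, hcg1=hcg1, hcg2=hcg2,
                     interval_hours=interval, outcome=outcome, **kw)


@pytest.fixture(scope="session")
def m6np_like():
    return load_builtin("m6np_like")


@pytest.fixture(scope="session")
def m4_like():
    return load_builtin("m4_like")


@pytest.fixture(scope="session")
def small_cohort():
    """Descriptive-mode synthetic cohort, small enough for fast tests."""
    cohort, truth = generate_cohort(default_params(seed=7, n=2000))
    return cohort, truth


@pytest.fixture
def toy_inclusion_cohort():
    """Ten records: six conforming, one each at 20 h and 80 h, one GTD and
    one lost-to-follow-up (both in-window)."""
    records = [make_record(id=f"t{i}", interval=48.0) for i in range(6)]
    records.append(make_record(id="t_short", interval=20.0))
    records.append(make_record(id="t_long", interval=80.0))
    records.append(make_record(id="t_gtd", interval=48.0, outcome="gtd"))
    records.append(make_record(id="t_lost", interval=48.0, outcome="lost"))
    return Cohort.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
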