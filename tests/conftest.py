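import numpy as np
import pytest

from blastodbn import DiscreteDBN, TraceBranch, make_reference_fixture, simulate_cohort


def make_branch(times, values, channel="YAP", d1=12.0, d2=24.0, end=36.0, t0=0.0, **kw):
    """A single-channel trace branch with round division times."""
    return TraceBranch(
        embryo_id="e0",
        batch_id="B1",
        lineage_id=1,
        branch_code="aa",
        samples={channel: (np.asarray(times, float), np.asarray(values, float))},
        division_times=(d1, d2),
        span=(t0, end),
        **kw,
    )


@pytest.fixture(scope="session")
def f1():
    return make_reference_fixture("F1")


@pytest.fixture(scope="session")
def f2():
    return make_reference_fixture("F2")


@pytest.fixture(scope="session")
def f3():
    return make_reference_fixture("F3")


@pytest.fixture(scope="session")
def f1_results(f1):
    return f1.to_results()


@pytest.fixture(scope="session")
def f2_results(f2):
    return f2.to_results()


@pytest.fixture(scope="session")
def f3_results(f3):
    return f3.to_results()


@pytest.fixture(scope="session")
def small_cohort_df(f1_results):
    """50 embryos of (Y, S) trajectories sampled from the F1 fixture."""
    return simulate_cohort(f1_results, 50, seed=42).to_frame()


@pytest.fixture(scope="session")
def fitted_m3(small_cohort_df):
    return DiscreteDBN("M3", small_cohort_df, "S").fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
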