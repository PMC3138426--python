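import pytest

from desr import (
    DesrThresholds,
    DualHypotheses,
    TrinomialRates,
    load_cohort,
    load_decision_cells,
    load_threshold_fixture,
)
from desr.design import Verdict

#: printed verdict letters -> final verdicts ("?" = continued, no stage-II data)
ACTIVITY = {
    "Y": Verdict.REJECT_NULL,
    "N": Verdict.ACCEPT_NULL,
    "P": Verdict.INDETERMINATE,
    "?": Verdict.INDETERMINATE,
}


@pytest.fixture(scope="session")
def hyps46():
    return DualHypotheses(r_nul=0.05, r_alt=0.2, epd_nul=0.6, epd_alt=0.4)


@pytest.fixture(scope="session")
def hyps35():
    return DualHypotheses(r_nul=0.05, r_alt=0.2, epd_nul=0.5, epd_alt=0.3)


@pytest.fixture(scope="session")
def th46():
    """Fleming-sized DESR bounds for the (epd_alt, epd_nul) = (0.4, 0.6) set."""
    return DesrThresholds(n1=15, n2=15, s_r=1, s_p=8, a_r=4, a_p=14)


@pytest.fixture(scope="session")
def th35():
    return DesrThresholds(n1=15, n2=15, s_r=1, s_p=6, a_r=4, a_p=11)


@pytest.fixture(scope="session")
def null46():
    return TrinomialRates(0.05, 0.6)


@pytest.fixture(scope="session")
def fleming_cohort():
    return load_cohort("fleming_cohort")


@pytest.fixture(scope="session")
def gehan_cohort():
    return load_cohort("gehan_cohort")


@pytest.fixture(scope="session")
def fleming_cells():
    return load_decision_cells("fleming_cohort")


@pytest.fixture(scope="session")
def gehan_cells():
    return load_decision_cells("gehan_cohort")


@pytest.fixture(scope="session")
def gehan_tables():
    return {
        "epd46": load_threshold_fixture("gehan_epd46"),
        "epd35": load_threshold_fixture("gehan_epd35"),
    }
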