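"""Core domain types and the DESR decision rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desr import (
    Decision,
    DesrThresholds,
    DualHypotheses,
    TrialRecord,
    TrinomialRates,
    ValidationError,
    decide_desr,
)
from desr.design import Verdict


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(r_nul=0.2, r_alt=0.05, epd_nul=0.6, epd_alt=0.4), "r_nul"),
        (dict(r_nul=0.05, r_alt=0.2, epd_nul=0.4, epd_alt=0.6), "epd_alt"),
        (dict(r_nul=0.05, r_alt=0.5, epd_nul=0.6, epd_alt=0.4), "r_alt + epd_nul"),
        (dict(r_nul=0.0, r_alt=0.2, epd_nul=0.6, epd_alt=0.4), "r_nul"),
    ],
)
def test_dual_hypotheses_invariants(kwargs, field):
    with pytest.raises(ValidationError, match=field.replace("+", r"\+")):
        DualHypotheses(**kwargs)


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(n1=15, n2=15, s_r=16, s_p=8, a_r=17, a_p=14), "s_r"),
        (dict(n1=15, n2=15, s_r=1, s_p=17, a_r=4, a_p=14), "s_p"),
        (dict(n1=15, n2=15, s_r=5, s_p=8, a_r=5, a_p=14), "a_r"),
        (dict(n1=15, n2=15, s_r=1, s_p=8, a_r=4, a_p=31), "a_p"),
    ],
)
def test_thresholds_invariants(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        DesrThresholds(**kwargs)


def test_thresholds_degenerate_encodings_are_legal():
    # s_p = n1+1: never stop on progression; a_p = -1: never reject on it
    th = DesrThresholds(n1=15, n2=15, s_r=1, s_p=16, a_r=4, a_p=-1)
    assert th.s_p == 16 and th.a_p == -1


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(trial_id="x", n1=15, r1=10, p1=6), "r1 \\+ p1"),
        (dict(trial_id="x", n1=15, r1=1, p1=6, n_tot=30, r_tot=0, p_tot=12), "r_tot"),
        (dict(trial_id="x", n1=15, r1=1, p1=6, n_tot=14, r_tot=2, p_tot=7), "n_tot"),
        (dict(trial_id="x", n1=15, r1=1, p1=6, n_tot=30, r_tot=2), "all present"),
    ],
)
def test_trial_record_invariants(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        TrialRecord(**kwargs)


def test_decision_invariant():
    with pytest.raises(ValidationError):
        Decision(stage1_stop=True, final=Verdict.REJECT_NULL)


class TestDecideDesr:
    """Worked examples from the historical comparison cohort."""

    def test_stage1_stop(self, th46):
        # 0 responses, 10 progressions of 15: responses <= 1 and progressions >= 8
        rec = TrialRecord("3", n1=15, r1=0, p1=10)
        d = decide_desr(rec, th46)
        assert d.stage1_stop and d.final is Verdict.ACCEPT_NULL

    def test_rejection_via_low_progression(self, th46):
        # continued; 12/25 cumulative progressions <= 14 rejects the null
        rec = TrialRecord("13", n1=15, r1=1, p1=6, n_tot=25, r_tot=1, p_tot=12)
        d = decide_desr(rec, th46)
        assert not d.stage1_stop and d.final is Verdict.REJECT_NULL

    def test_indeterminate_without_stage2(self, th46):
        rec = TrialRecord("2", n1=15, r1=0, p1=1)
        d = decide_desr(rec, th46)
        assert not d.stage1_stop and d.final is Verdict.INDETERMINATE

    def test_absolute_bounds_under_underaccrual(self, th46):
        # n1 = 14 instead of 15: the stage-1 bounds apply unchanged
        rec = TrialRecord("7", n1=14, r1=0, p1=7)
        assert not decide_desr(rec, th46).stage1_stop
        rec8 = TrialRecord("7b", n1=14, r1=0, p1=8)
        assert decide_desr(rec8, th46).stage1_stop

    def test_determinism(self, th46):
        rec = TrialRecord("12", n1=15, r1=7, p1=6, n_tot=30, r_tot=13, p_tot=13)
        assert decide_desr(rec, th46) == decide_desr(rec, th46)


@settings(max_examples=200, derandomize=True)
@given(
    r1=st.integers(0, 15),
    p1=st.integers(0, 15),
    s_r=st.integers(0, 15),
    s_p=st.integers(0, 16),
)
def test_stage1_stop_monotonicity(r1, p1, s_r, s_p):
    """More responses can only cancel a stop; more progressions can only
    trigger one."""
    if r1 + p1 > 15:
        return
    th = DesrThresholds(n1=15, n2=15, s_r=s_r, s_p=s_p, a_r=s_r + 1, a_p=-1)
    base = decide_desr(TrialRecord("t", 15, r1, p1), th).stage1_stop
    if r1 + 1 + p1 <= 15:
        more_r = decide_desr(TrialRecord("t", 15, r1 + 1, p1), th).stage1_stop
        assert not (more_r and not base)
    if r1 + p1 + 1 <= 15:
        more_p = decide_desr(TrialRecord("t", 15, r1, p1 + 1), th).stage1_stop
        assert not (base and not more_p)


def test_full_fleming_table_reproduction(fleming_cohort, fleming_cells, th46, th35):
    """Every printed DESR stage-I-stop and drug-activity cell of the
    Fleming comparison table is reproduced by the bundled thresholds, for
    both EPD parameter sets."""
    from conftest import ACTIVITY

    for rec, (_, row) in zip(fleming_cohort, fleming_cells.iterrows()):
        for th, stop_col, act_col in (
            (th46, "desr46_stop", "desr46_activity"),
            (th35, "desr35_stop", "desr35_activity"),
        ):
            d = decide_desr(rec, th)
            assert d.stage1_stop == (row[stop_col] == "Y"), (rec.trial_id, stop_col)
            assert d.final is ACTIVITY[row[act_col]], (rec.trial_id, act_col)
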