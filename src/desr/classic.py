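"""Single-endpoint (response-only) two-stage designs: Fleming and Gehan.

These are the historical comparators for the dual-endpoint rule.  The
Fleming-style design tests H_nul: r <= r_nul against H_alt: r >= r_alt with
fixed stage sizes and integer response bounds; its bounds are taken as
inputs here, not derived.  The Gehan design stops at stage I only when zero
responses are seen (stage-I size chosen so a drug with the response rate of
interest is unlikely to show none), and sizes stage II for estimation
precision rather than testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .design import Decision, TrialRecord, ValidationError, Verdict, _check

__all__ = [
    "FlemingThresholds",
    "GehanDesign",
    "gehan_stage1_size",
    "gehan_stage2_size",
    "decide_fleming",
    "decide_gehan",
]


@dataclass(frozen=True)
class FlemingThresholds:
    """Integer bounds of a Fleming-style two-stage response design.

    Early acceptance of the null when stage-I responses ``<= accept_bound``;
    optional early rejection when ``>= early_reject_bound`` (disabled by
    default — the historical cohort never invoked it); final rejection when
    cumulative responses ``>= final_reject_bound``.
    """

    n1: int
    accept_bound: int
    n2: int
    final_reject_bound: int
    early_reject_bound: Optional[int] = None

    def __post_init__(self) -> None:
        _check(self.n1 >= 1, f"n1 must be >= 1, got {self.n1}")
        _check(self.n2 >= 0, f"n2 must be >= 0, got {self.n2}")
        _check(
            self.accept_bound < self.final_reject_bound <= self.n1 + self.n2,
            f"final_reject_bound must lie in (accept_bound, n1+n2], got {self.final_reject_bound}",
        )
        if self.early_reject_bound is not None:
            _check(
                self.accept_bound + 1 < self.early_reject_bound <= self.n1,
                "early_reject_bound must leave a continuation region within stage I",
            )


@dataclass(frozen=True)
class GehanDesign:
    """Parameters of a Gehan two-stage design.

    ``p_interest``/``beta`` size stage I; ``se_target`` sizes stage II; the
    final activity call uses the observed cumulative response rate against
    ``r_alt_eval`` (the rate of interest) — a configurable evaluation
    convention, since Gehan's procedure itself is estimation-only.
    """

    p_interest: float = 0.2
    beta: float = 0.05
    se_target: float = 0.05
    r_alt_eval: float = 0.2

    def __post_init__(self) -> None:
        _check(0.0 < self.p_interest < 1.0, f"p_interest must lie in (0,1), got {self.p_interest}")
        _check(0.0 < self.beta < 1.0, f"beta must lie in (0,1), got {self.beta}")
        _check(self.se_target > 0.0, f"se_target must be > 0, got {self.se_target}")
        _check(0.0 < self.r_alt_eval <= 1.0, f"r_alt_eval must lie in (0,1], got {self.r_alt_eval}")


def gehan_stage1_size(p_interest: float, beta: float) -> int:
    """Smallest stage-I size n with ``(1 - p_interest)^n <= beta``.

    With this n, a drug whose true response rate is ``p_interest`` shows
    zero responses (and is discarded) with probability at most ``beta``.
    """
    if not (0.0 < p_interest < 1.0):
        raise ValidationError(f"p_interest must lie in (0, 1), got {p_interest}")
    if not (0.0 < beta < 1.0):
        raise ValidationError(f"beta must lie in (0, 1), got {beta}")
    n = 1
    while (1.0 - p_interest) ** n > beta:
        n += 1
    return n


def gehan_stage2_size(n1: int, r1: int, se_target: float) -> int:
    """Stage-II size for the desired standard error of the response-rate
    estimate, given ``r1`` stage-I responses.

    A conservative plug-in rate ``p~`` — the exact (Clopper–Pearson)
    one-sided upper 75% confidence bound for ``r1/n1`` — enters the
    binomial-variance formula::

        n2 = max(0, ceil(p~ (1 - p~) / se_target**2 - n1))
    """
    _check(0 <= r1 <= n1, f"r1 must lie in [0, n1], got {r1}")
    _check(se_target > 0.0, f"se_target must be > 0, got {se_target}")
    if r1 == n1:
        p_up = 1.0
    else:
        p_up = float(stats.beta.ppf(0.75, r1 + 1, n1 - r1))
    total = p_up * (1.0 - p_up) / se_target**2
    return max(0, math.ceil(total - n1))


def decide_fleming(record: TrialRecord, th: FlemingThresholds) -> Decision:
    """Apply a Fleming-style response-count rule to one trial.

    Final rejection uses the absolute cumulative bound even for trials that
    under-accrued stage II (the convention under which every published cell
    of the comparison cohort is reproduced).
    """
    if record.r1 <= th.accept_bound:
        return Decision(stage1_stop=True, final=Verdict.ACCEPT_NULL)
    if th.early_reject_bound is not None and record.r1 >= th.early_reject_bound:
        # early rejection ends the trial at stage I but is a rejection, not
        # an acceptance, so it is not modelled as a stage-1 (futility) stop
        return Decision(stage1_stop=False, final=Verdict.REJECT_NULL)
    if not record.has_stage2:
        return Decision(stage1_stop=False, final=Verdict.INDETERMINATE)
    if record.r_tot >= th.final_reject_bound:
        return Decision(stage1_stop=False, final=Verdict.REJECT_NULL)
    return Decision(stage1_stop=False, final=Verdict.ACCEPT_NULL)


def decide_gehan(record: TrialRecord, design: GehanDesign) -> Decision:
    """Apply the Gehan rule to one trial.

    Stage-I stop iff zero responses; otherwise the drug is called active
    when the observed cumulative response rate reaches ``r_alt_eval``.
    """
    if record.r1 == 0:
        return Decision(stage1_stop=True, final=Verdict.ACCEPT_NULL)
    if not record.has_stage2:
        return Decision(stage1_stop=False, final=Verdict.INDETERMINATE)
    if record.r_tot / record.n_tot >= design.r_alt_eval:
        return Decision(stage1_stop=False, final=Verdict.REJECT_NULL)
    return Decision(stage1_stop=False, final=Verdict.ACCEPT_NULL)
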