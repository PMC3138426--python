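"""Domain types and decision rules for the Dual Endpoint Stopping Rule (DESR).

A DESR trial observes two binary events per patient — tumour response and
early progressive disease (EPD, progression at the first on-treatment
assessment) — so each patient falls into one of three categories
(response / early progression / other).  The trial accrues ``n1`` patients in
stage I and, barring an early stop, ``n2`` more in stage II.

Stage-I futility stop (accept the null hypothesis that the drug is
uninteresting) occurs when responses are low *and* progressions are high::

    r1 <= s_r  and  p1 >= s_p

At the end of stage II the null hypothesis is rejected (drug declared
active) when cumulative responses are high *or* cumulative progressions are
low::

    r_tot >= a_r  or  p_tot <= a_p

All bounds are inclusive integer counts and are applied as absolute counts
even when a trial under- or over-accrued relative to ``n1 + n2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "ValidationError",
    "DualHypotheses",
    "DesrThresholds",
    "TrinomialRates",
    "TrialRecord",
    "Verdict",
    "Decision",
    "decide_desr",
]


class ValidationError(ValueError):
    """Raised when a domain-type invariant is violated; names the field."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class DualHypotheses:
    """Rate parameters defining the null and alternative hypotheses.

    The null hypothesis (uninteresting drug) is ``r <= r_nul and
    epd >= epd_nul``; the alternative (drug of interest) is ``r >= r_alt or
    epd <= epd_alt``.

    Parameters
    ----------
    r_nul, r_alt : float
        Response rates of disinterest and interest, ``0 < r_nul < r_alt < 1``.
    epd_nul, epd_alt : float
        Early-progression rates of disinterest and interest,
        ``0 < epd_alt < epd_nul < 1``.
    """

    r_nul: float
    r_alt: float
    epd_nul: float
    epd_alt: float

    def __post_init__(self) -> None:
        for name in ("r_nul", "r_alt", "epd_nul", "epd_alt"):
            v = getattr(self, name)
            _check(0.0 < v < 1.0, f"{name} must lie in (0, 1), got {v}")
        _check(self.r_nul < self.r_alt, f"r_nul ({self.r_nul}) must be < r_alt ({self.r_alt})")
        _check(
            self.epd_alt < self.epd_nul,
            f"epd_alt ({self.epd_alt}) must be < epd_nul ({self.epd_nul})",
        )
        _check(
            self.r_alt + self.epd_nul <= 1.0 + 1e-12,
            f"r_alt + epd_nul must be <= 1 for a valid trinomial, got {self.r_alt + self.epd_nul}",
        )


@dataclass(frozen=True)
class DesrThresholds:
    """Stage sizes and the four integer decision bounds of a DESR design.

    Parameters
    ----------
    n1, n2 : int
        Stage-I and stage-II sample sizes.
    s_r : int
        Stage-I stop requires responses ``<= s_r``.
    s_p : int
        Stage-I stop requires progressions ``>= s_p``; ``s_p = n1 + 1``
        encodes "never stop on progression".
    a_r : int
        Final rejection of the null when cumulative responses ``>= a_r``.
    a_p : int
        Final rejection of the null when cumulative progressions ``<= a_p``;
        ``a_p = -1`` encodes "never reject on progression".
    """

    n1: int
    n2: int
    s_r: int
    s_p: int
    a_r: int
    a_p: int

    def __post_init__(self) -> None:
        _check(self.n1 >= 1, f"n1 must be >= 1, got {self.n1}")
        _check(self.n2 >= 0, f"n2 must be >= 0, got {self.n2}")
        _check(0 <= self.s_r <= self.n1, f"s_r must lie in [0, n1], got {self.s_r}")
        _check(0 <= self.s_p <= self.n1 + 1, f"s_p must lie in [0, n1+1], got {self.s_p}")
        _check(
            self.s_r < self.a_r <= self.n1 + self.n2,
            f"a_r must lie in (s_r, n1+n2], got {self.a_r}",
        )
        _check(
            -1 <= self.a_p <= self.n1 + self.n2,
            f"a_p must lie in [-1, n1+n2], got {self.a_p}",
        )


@dataclass(frozen=True)
class TrinomialRates:
    """True per-patient outcome probabilities (response, early progression).

    The implied third category ("other": stable disease, late progression,
    not evaluable, ...) has probability ``1 - p_r - p_p``.
    """

    p_r: float
    p_p: float

    def __post_init__(self) -> None:
        _check(self.p_r >= 0.0, f"p_r must be >= 0, got {self.p_r}")
        _check(self.p_p >= 0.0, f"p_p must be >= 0, got {self.p_p}")
        _check(
            self.p_r + self.p_p <= 1.0 + 1e-12,
            f"p_r + p_p must be <= 1, got {self.p_r + self.p_p}",
        )

    @property
    def p_other(self) -> float:
        return max(0.0, 1.0 - self.p_r - self.p_p)


@dataclass(frozen=True)
class TrialRecord:
    """Observed counts for one trial, as printed in published trial tables.

    Stage-II counts, when present, are cumulative over both stages (the
    convention of the source tables); increments are derived, never stored.
    The three cumulative fields are all present or all absent.
    """

    trial_id: str
    n1: int
    r1: int
    p1: int
    n_tot: Optional[int] = None
    r_tot: Optional[int] = None
    p_tot: Optional[int] = None
    investigator_stopped: bool = False

    def __post_init__(self) -> None:
        _check(self.n1 >= 1, f"n1 must be >= 1 (trial {self.trial_id})")
        _check(self.r1 >= 0, f"r1 must be >= 0 (trial {self.trial_id})")
        _check(self.p1 >= 0, f"p1 must be >= 0 (trial {self.trial_id})")
        _check(
            self.r1 + self.p1 <= self.n1,
            f"r1 + p1 must be <= n1 (trial {self.trial_id})",
        )
        cum = (self.n_tot, self.r_tot, self.p_tot)
        if any(v is not None for v in cum):
            _check(
                all(v is not None for v in cum),
                f"n_tot/r_tot/p_tot must be all present or all absent (trial {self.trial_id})",
            )
            _check(self.n_tot >= self.n1, f"n_tot must be >= n1 (trial {self.trial_id})")
            _check(self.r_tot >= self.r1, f"r_tot must be >= r1 (trial {self.trial_id})")
            _check(self.p_tot >= self.p1, f"p_tot must be >= p1 (trial {self.trial_id})")
            _check(
                self.r_tot + self.p_tot <= self.n_tot,
                f"r_tot + p_tot must be <= n_tot (trial {self.trial_id})",
            )

    @property
    def has_stage2(self) -> bool:
        return self.n_tot is not None


class Verdict(str, Enum):
    """Final conclusion of a stopping rule applied to one trial."""

    ACCEPT_NULL = "accept_null"
    REJECT_NULL = "reject_null"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Decision:
    """Verdict of a rule set on one trial.

    ``stage1_stop`` implies ``final == ACCEPT_NULL``; ``INDETERMINATE``
    occurs only for trials that continue past stage I but report no
    stage-II counts.
    """

    stage1_stop: bool
    final: Verdict

    def __post_init__(self) -> None:
        if self.stage1_stop:
            _check(
                self.final is Verdict.ACCEPT_NULL,
                "final must be accept_null when stage1_stop is true",
            )
        elif self.final is Verdict.INDETERMINATE:
            pass  # legal only without stage-II data; enforced by constructors


def decide_desr(record: TrialRecord, th: DesrThresholds) -> Decision:
    """Apply a DESR design to one trial's observed counts.

    The trial stops at stage I (accepting the null) iff
    ``r1 <= s_r and p1 >= s_p``.  Otherwise the null is rejected iff
    ``r_tot >= a_r or p_tot <= a_p``; with no cumulative counts the final
    verdict is indeterminate.  Bounds are absolute counts, applied unchanged
    when the realised accrual differs from ``n1 + n2`` (under-accrued trials
    in the source cohorts are judged this way).

    Parameters
    ----------
    record : TrialRecord
    th : DesrThresholds

    Returns
    -------
    Decision
    """
    if record.r1 <= th.s_r and record.p1 >= th.s_p:
        return Decision(stage1_stop=True, final=Verdict.ACCEPT_NULL)
    if not record.has_stage2:
        return Decision(stage1_stop=False, final=Verdict.INDETERMINATE)
    if record.r_tot >= th.a_r or record.p_tot <= th.a_p:
        return Decision(stage1_stop=False, final=Verdict.REJECT_NULL)
    return Decision(stage1_stop=False, final=Verdict.ACCEPT_NULL)
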