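"""Seedable Monte Carlo simulation of DESR trials.

Serves two purposes: an independent stochastic check on the exact
enumeration engine, and a generator of synthetic trial-count cohorts so the
decision and comparison layers are testable without any external data.

Every function takes an explicit integer seed (or an already-constructed
generator); there is no module or global RNG state, and a fixed seed yields
byte-identical output across runs.  Alternative-hypothesis mixtures draw
the drug class once per simulated trial — a population of drugs, each with
its own fixed rates — not per patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .design import (
    Decision,
    DesrThresholds,
    TrialRecord,
    TrinomialRates,
    Verdict,
    _check,
)
from .exact import AltMixture, OperatingCharacteristics

__all__ = ["SimulationResult", "simulate_trial", "estimate_oc", "generate_trial_records"]


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo estimates of operating characteristics.

    ``standard_errors`` carries one binomial standard error per estimated
    field (``en`` errors are ``n2`` times the corresponding ``pes`` error,
    by the accrual identity).
    """

    n_reps: int
    estimates: OperatingCharacteristics
    standard_errors: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        _check(self.n_reps >= 1, f"n_reps must be >= 1, got {self.n_reps}")
        _check(all(v >= 0 for v in self.standard_errors.values()), "standard errors must be >= 0")


def _probs(rates: TrinomialRates) -> list[float]:
    return [rates.p_r, rates.p_p, rates.p_other]


def simulate_trial(
    th: DesrThresholds,
    rates: TrinomialRates,
    rng: Union[int, np.random.Generator],
) -> tuple[Decision, int]:
    """Simulate one DESR trial; returns the decision and patients accrued.

    Stage-I counts are drawn from Trinomial(n1, rates); if the stop rule
    does not fire, an independent Trinomial(n2, rates) stage-II draw is
    added and the final rule applied.  Accrual is ``n1`` or ``n1 + n2``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r1, p1, _ = rng.multinomial(th.n1, _probs(rates))
    if r1 <= th.s_r and p1 >= th.s_p:
        return Decision(stage1_stop=True, final=Verdict.ACCEPT_NULL), th.n1
    r2, p2, _ = rng.multinomial(th.n2, _probs(rates))
    if r1 + r2 >= th.a_r or p1 + p2 <= th.a_p:
        final = Verdict.REJECT_NULL
    else:
        final = Verdict.ACCEPT_NULL
    return Decision(stage1_stop=False, final=final), th.n1 + th.n2


def _sim_outcomes(
    th: DesrThresholds, counts1: np.ndarray, counts2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised stop/reject indicators from per-replicate count arrays."""
    stop = (counts1[:, 0] <= th.s_r) & (counts1[:, 1] >= th.s_p)
    r_tot = counts1[:, 0] + counts2[:, 0]
    p_tot = counts1[:, 1] + counts2[:, 1]
    reject = (~stop) & ((r_tot >= th.a_r) | (p_tot <= th.a_p))
    return stop, reject


def estimate_oc(
    th: DesrThresholds,
    null: TrinomialRates,
    alt: AltMixture,
    n_reps: int,
    seed: int,
) -> SimulationResult:
    """Monte Carlo estimate of a design's operating characteristics.

    ``n_reps`` independent replicates are run under the null configuration
    and another ``n_reps`` under the alternative mixture (component drawn
    per replicate with the mixture weights).  Standard errors are binomial,
    ``sqrt(p_hat (1 - p_hat) / n_reps)``.
    """
    _check(n_reps >= 1, f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)

    # null side
    c1 = rng.multinomial(th.n1, _probs(null), size=n_reps)
    c2 = rng.multinomial(th.n2, _probs(null), size=n_reps)
    stop_n, rej_n = _sim_outcomes(th, c1, c2)

    # alternative side: per-replicate component draw
    comp = rng.choice(len(alt.components), size=n_reps, p=alt.weights)
    c1a = np.empty((n_reps, 3), dtype=np.int64)
    c2a = np.empty((n_reps, 3), dtype=np.int64)
    for idx, rates in enumerate(alt.rates):
        mask = comp == idx
        k = int(mask.sum())
        if k:
            c1a[mask] = rng.multinomial(th.n1, _probs(rates), size=k)
            c2a[mask] = rng.multinomial(th.n2, _probs(rates), size=k)
    stop_a, rej_a = _sim_outcomes(th, c1a, c2a)

    def _se(p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / n_reps))

    alpha = float(rej_n.mean())
    power = float(rej_a.mean())
    pes_nul = float(stop_n.mean())
    pes_alt = float(stop_a.mean())
    est = OperatingCharacteristics(
        alpha=alpha,
        power=power,
        pes_nul=pes_nul,
        en_nul=th.n1 + th.n2 * (1.0 - pes_nul),
        pes_alt=pes_alt,
        en_alt=th.n1 + th.n2 * (1.0 - pes_alt),
    )
    ses = {
        "alpha": _se(alpha),
        "power": _se(power),
        "pes_nul": _se(pes_nul),
        "en_nul": th.n2 * _se(pes_nul),
        "pes_alt": _se(pes_alt),
        "en_alt": th.n2 * _se(pes_alt),
    }
    return SimulationResult(n_reps=n_reps, estimates=est, standard_errors=ses, seed=seed)


def generate_trial_records(
    n_trials: int,
    rates: TrinomialRates,
    n1: int,
    n2: int,
    seed: int,
) -> list[TrialRecord]:
    """Generate synthetic trial records from the trinomial outcome model.

    Each record carries stage-I counts and full cumulative totals over
    ``n1 + n2`` patients (as if the trial accrued both stages, the way the
    historical cohorts report even investigator-continued trials), and
    satisfies every :class:`~desr.design.TrialRecord` invariant.
    """
    _check(n_trials >= 1, f"n_trials must be >= 1, got {n_trials}")
    _check(n1 >= 1 and n2 >= 0, "n1 must be >= 1 and n2 >= 0")
    rng = np.random.default_rng(seed)
    c1 = rng.multinomial(n1, _probs(rates), size=n_trials)
    c2 = rng.multinomial(n2, _probs(rates), size=n_trials)
    records = []
    for i in range(n_trials):
        records.append(
            TrialRecord(
                trial_id=f"sim-{i + 1}",
                n1=n1,
                r1=int(c1[i, 0]),
                p1=int(c1[i, 1]),
                n_tot=n1 + n2,
                r_tot=int(c1[i, 0] + c2[i, 0]),
                p_tot=int(c1[i, 1] + c2[i, 1]),
            )
        )
    return records
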