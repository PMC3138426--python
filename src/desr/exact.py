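"""Exact operating characteristics of DESR designs by trinomial enumeration.

Stage-I outcomes are Trinomial(n1; p_r, p_p, 1-p_r-p_p) counts (responses,
early progressions); stage-II outcomes, conditional on continuation, are an
independent Trinomial(n2; ...) draw (patients are i.i.d. given the true
rates).  All probabilities below are computed by exact summation over the
joint count lattice — no normal approximations — with log-space category
probabilities for numerical stability and a fixed summation order so results
are bit-reproducible.

Type I error (alpha) is evaluated at the point null (r_nul, epd_nul).
Power follows the borderline-value construction: a drug of interest is not
assumed better than the alternative boundary on *either* endpoint, modelled
as a mixture (50/50 by default) of the two boundary configurations
(r_alt, epd_nul) and (r_nul, epd_alt).  Both the null point and the mixture
are overridable parameters of :func:`oc_for_design`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Optional

import numpy as np
from scipy import stats

from .design import (
    DesrThresholds,
    DualHypotheses,
    TrinomialRates,
    ValidationError,
    _check,
)

__all__ = [
    "OperatingCharacteristics",
    "AltMixture",
    "TwoStageBinomialOC",
    "trinomial_pmf",
    "trinomial_pmf_matrix",
    "prob_stage1_stop",
    "prob_reject",
    "expected_sample_size",
    "oc_for_design",
    "single_endpoint_oc",
]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Exact (or estimated) operating characteristics of a two-stage design.

    Attributes
    ----------
    alpha : float
        Probability of rejecting the null when the null configuration holds.
    power : float
        Probability of rejecting the null under the alternative mixture.
    pes_nul, pes_alt : float
        Probability of early stopping (trial ends after stage I) under the
        null and the alternative.
    en_nul, en_alt : float
        Expected number of patients accrued, ``n1 + n2 * (1 - pes)``.
    """

    alpha: float
    power: float
    pes_nul: float
    en_nul: float
    pes_alt: float
    en_alt: float

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "power": self.power,
            "pes_nul": self.pes_nul,
            "en_nul": self.en_nul,
            "pes_alt": self.pes_alt,
            "en_alt": self.en_alt,
        }


@dataclass(frozen=True)
class AltMixture:
    """A mixture of trinomial configurations describing drugs of interest."""

    components: tuple[tuple[TrinomialRates, float], ...]

    def __post_init__(self) -> None:
        _check(len(self.components) >= 1, "components must be nonempty")
        ws = [w for _, w in self.components]
        _check(all(w >= 0.0 for w in ws), "weights must be >= 0")
        _check(abs(sum(ws) - 1.0) <= 1e-12, f"weights must sum to 1, got {sum(ws)}")

    @classmethod
    def borderline(cls, hyps: DualHypotheses, weight_response: float = 0.5) -> "AltMixture":
        """Borderline-value mixture: each drug of interest sits at the
        alternative boundary of exactly one endpoint.

        Component 1 responds well with null-level progression,
        ``(r_alt, epd_nul)``; component 2 rarely responds but rarely
        progresses early, ``(r_nul, epd_alt)``.
        """
        return cls(
            components=(
                (TrinomialRates(hyps.r_alt, hyps.epd_nul), weight_response),
                (TrinomialRates(hyps.r_nul, hyps.epd_alt), 1.0 - weight_response),
            )
        )

    @property
    def rates(self) -> list[TrinomialRates]:
        return [r for r, _ in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])


def trinomial_pmf(n: int, k_r: int, k_p: int, rates: TrinomialRates) -> float:
    """Probability of exactly ``k_r`` responses and ``k_p`` early
    progressions among ``n`` patients.

    Computed in log space; stable for ``n`` in the hundreds.
    """
    if not (0 <= k_r and 0 <= k_p and k_r + k_p <= n):
        raise ValidationError(
            f"counts out of range: k_r={k_r}, k_p={k_p}, n={n}"
        )
    return float(trinomial_pmf_matrix(n, rates)[k_r, k_p])


def trinomial_pmf_matrix(n: int, rates: TrinomialRates) -> np.ndarray:
    """Full trinomial pmf on the count lattice.

    Returns an ``(n+1, n+1)`` array ``M`` with ``M[k_r, k_p]`` the
    probability of that outcome; entries with ``k_r + k_p > n`` are zero.
    """
    kr = np.arange(n + 1)
    KR, KP = np.meshgrid(kr, kr, indexing="ij")
    KO = n - KR - KP
    valid = KO >= 0
    lgam = np.array([lgamma(i + 1.0) for i in range(n + 1)])
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = lgam[n] - lgam[KR] - lgam[KP] - lgam[np.where(valid, KO, 0)]
        for k, p in ((KR, rates.p_r), (KP, rates.p_p), (np.where(valid, KO, 0), rates.p_other)):
            # 0 * log(0) = 0 by convention (category never drawn)
            term = np.where(k > 0, k * np.log(np.maximum(p, 1e-300)), 0.0)
            logp = logp + term
    out = np.where(valid, np.exp(logp), 0.0)
    # impossible outcomes under degenerate rates underflow to exactly 0
    return out


def _stop_mask(n1: int, s_r: int, s_p: int) -> np.ndarray:
    kr = np.arange(n1 + 1)
    KR, KP = np.meshgrid(kr, kr, indexing="ij")
    return (KR <= s_r) & (KP >= s_p) & (KR + KP <= n1)


def prob_stage1_stop(th: DesrThresholds, rates: TrinomialRates) -> float:
    """Exact probability of the stage-I futility stop
    {responses <= s_r and progressions >= s_p} over Trinomial(n1, rates)."""
    pmf1 = trinomial_pmf_matrix(th.n1, rates)
    return float(pmf1[_stop_mask(th.n1, th.s_r, th.s_p)].sum())


def _stage2_or_table(n2: int, rates: TrinomialRates) -> np.ndarray:
    """G[x, y] = P(j_r >= x or j_p <= y) over Trinomial(n2, rates),
    for x in 0..n2+1 and y in -1..n2 (index y+1).

    Built from the complement P(j_r <= x-1 and j_p >= y+1) via 2-D
    prefix/suffix sums of the stage-II pmf.
    """
    pmf2 = trinomial_pmf_matrix(n2, rates)
    # C[x, y] = P(j_r <= x and j_p >= y), x,y in 0..n2
    C = np.cumsum(np.cumsum(pmf2[:, ::-1], axis=1)[:, ::-1], axis=0)
    G = np.empty((n2 + 2, n2 + 2))
    for x in range(n2 + 2):
        for yi in range(n2 + 2):
            y = yi - 1  # threshold a_p - k_p
            xr = x - 1  # complement needs j_r <= x-1
            yr = y + 1  # and j_p >= y+1
            if xr < 0 or yr > n2:
                comp = 0.0
            else:
                comp = C[min(xr, n2), max(yr, 0)]
            G[x, yi] = 1.0 - comp
    return G


def prob_reject(th: DesrThresholds, rates: TrinomialRates) -> float:
    """Exact probability of rejecting the null hypothesis.

    Sums, over every stage-I state outside the stop region, the state
    probability times the independent stage-II probability of
    {cumulative responses >= a_r or cumulative progressions <= a_p}.
    """
    pmf1 = trinomial_pmf_matrix(th.n1, rates)
    stop = _stop_mask(th.n1, th.s_r, th.s_p)
    G = _stage2_or_table(th.n2, rates)
    kr = np.arange(th.n1 + 1)
    KR, KP = np.meshgrid(kr, kr, indexing="ij")
    X = np.clip(th.a_r - KR, 0, th.n2 + 1)
    Y = np.clip(th.a_p - KP, -1, th.n2) + 1
    cont = (~stop) & (KR + KP <= th.n1)
    return float((pmf1[cont] * G[X[cont], Y[cont]]).sum())


def expected_sample_size(th: DesrThresholds, rates: TrinomialRates) -> float:
    """Expected number of patients accrued: ``n1 + n2 * (1 - PES)``."""
    return th.n1 + th.n2 * (1.0 - prob_stage1_stop(th, rates))


def oc_for_design(
    th: DesrThresholds,
    hyps: DualHypotheses,
    alt: Optional[AltMixture] = None,
    null: Optional[TrinomialRates] = None,
) -> OperatingCharacteristics:
    """Exact operating characteristics of a DESR design.

    Parameters
    ----------
    th : DesrThresholds
    hyps : DualHypotheses
        Used for the default null point and borderline mixture.
    alt : AltMixture, optional
        Alternative-hypothesis configuration; defaults to the 50/50
        borderline mixture ``{(r_alt, epd_nul), (r_nul, epd_alt)}``.
    null : TrinomialRates, optional
        Null configuration for alpha; defaults to ``(r_nul, epd_nul)``.

    Returns
    -------
    OperatingCharacteristics
        ``power``, ``pes_alt`` and ``en_alt`` are weight-averaged over the
        mixture components; ``en = n1 + n2*(1 - pes)`` holds exactly on both
        sides.
    """
    if null is None:
        null = TrinomialRates(hyps.r_nul, hyps.epd_nul)
    if alt is None:
        alt = AltMixture.borderline(hyps)

    alpha = prob_reject(th, null)
    pes_nul = prob_stage1_stop(th, null)

    w = alt.weights
    power = float(sum(wi * prob_reject(th, ri) for ri, wi in alt.components))
    pes_alt = float(sum(wi * prob_stage1_stop(th, ri) for ri, wi in alt.components))

    return OperatingCharacteristics(
        alpha=alpha,
        power=power,
        pes_nul=pes_nul,
        en_nul=th.n1 + th.n2 * (1.0 - pes_nul),
        pes_alt=pes_alt,
        en_alt=th.n1 + th.n2 * (1.0 - pes_alt),
    )


@dataclass(frozen=True)
class TwoStageBinomialOC:
    """Reject probability, early-stop probability and expected N of a
    single-endpoint (binomial) two-stage design at one response rate."""

    reject_prob: float
    pes: float
    en: float


def single_endpoint_oc(
    n1: int,
    accept_bound: int,
    n2: int,
    final_reject_bound: int,
    p: float,
    reject_bound_stage1: Optional[int] = None,
) -> TwoStageBinomialOC:
    """Exact binomial operating characteristics of a two-stage
    single-endpoint design (Fleming-style) at true response rate ``p``.

    The trial stops early to accept the null if stage-I responses
    ``<= accept_bound``; optionally stops early to reject if
    ``>= reject_bound_stage1``.  Otherwise the null is rejected when
    cumulative responses ``>= final_reject_bound``.
    """
    _check(
        accept_bound < final_reject_bound,
        f"accept_bound ({accept_bound}) must be < final_reject_bound ({final_reject_bound})",
    )
    if reject_bound_stage1 is not None:
        _check(
            reject_bound_stage1 > accept_bound + 1,
            "reject_bound_stage1 must exceed accept_bound + 1 (a continuation region must exist)",
        )
    _check(0.0 <= p <= 1.0, f"p must lie in [0, 1], got {p}")

    pmf1 = stats.binom.pmf(np.arange(n1 + 1), n1, p)
    # stage-2 survival: P(Bin(n2, p) >= m), m in 0..n2+1
    sf2 = np.concatenate(([1.0], stats.binom.sf(np.arange(n2 + 1), n2, p)))

    reject = 0.0
    pes = 0.0
    for k in range(n1 + 1):
        if k <= accept_bound:
            pes += pmf1[k]
        elif reject_bound_stage1 is not None and k >= reject_bound_stage1:
            pes += pmf1[k]
            reject += pmf1[k]
        else:
            m = final_reject_bound - k
            tail = 1.0 if m <= 0 else (0.0 if m > n2 else sf2[m])
            reject += pmf1[k] * tail
    return TwoStageBinomialOC(
        reject_prob=float(reject),
        pes=float(pes),
        en=float(n1 + n2 * (1.0 - pes)),
    )
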