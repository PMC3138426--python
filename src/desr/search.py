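"""Exhaustive derivation of DESR thresholds under alpha/power constraints.

The search enumerates every bound quadruple (s_r, s_p, a_r, a_p) over

    s_r in [0, n1],  s_p in [0, n1 + 1]   (n1 + 1: never stop on progression)
    a_r in [s_r + 1, n1 + n2],  a_p in [-1, n1 + n2]   (-1: never reject)

computes exact operating characteristics for each candidate (the exact
engine drives the search; Monte Carlo is a verification tool only), keeps
the candidates with ``alpha <= alpha_max`` and ``power >= power_min``, and
returns the one preferred by an ordered criteria list.  The default
criteria favour high early stopping under the null, then low expected null
sample size, then high power; ties are broken by ascending (s_r, s_p, a_r,
a_p), so the search is deterministic.

The inner loop is vectorised: for a fixed stage-I stop region the rejection
probability over all (a_r, a_p) pairs is a weighted sum of shifted
stage-II tail tables, evaluated with one fancy-indexing pass per rate
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .design import DesrThresholds, DualHypotheses, TrinomialRates, ValidationError, _check
from .exact import (
    AltMixture,
    OperatingCharacteristics,
    _stage2_or_table,
    trinomial_pmf_matrix,
)

__all__ = ["SearchConstraints", "SearchResult", "TableRow", "search_thresholds", "derive_table"]

#: criterion name -> (extractor, sign); larger key is better
_CRITERIA: dict[str, Callable[[OperatingCharacteristics], float]] = {
    "max_pes_nul": lambda oc: oc.pes_nul,
    "min_en_nul": lambda oc: -oc.en_nul,
    "max_power": lambda oc: oc.power,
    "min_alpha": lambda oc: -oc.alpha,
    "min_en_alt": lambda oc: -oc.en_alt,
}

DEFAULT_SELECTION = ("max_pes_nul", "min_en_nul", "max_power")


@dataclass(frozen=True)
class SearchConstraints:
    """Feasibility constraints and selection criteria for the search.

    Parameters
    ----------
    alpha_max : float
        Maximum tolerated type I error (exact, at the point null).
    power_min : float
        Minimum required power (exact, under the alternative mixture).
    selection : tuple of str
        Ordered preference criteria applied to feasible candidates; any of
        ``max_pes_nul``, ``min_en_nul``, ``max_power``, ``min_alpha``,
        ``min_en_alt``.
    """

    alpha_max: float
    power_min: float
    selection: tuple[str, ...] = DEFAULT_SELECTION

    def __post_init__(self) -> None:
        _check(0.0 < self.alpha_max < 1.0, f"alpha_max must lie in (0, 1), got {self.alpha_max}")
        _check(0.0 < self.power_min < 1.0, f"power_min must lie in (0, 1), got {self.power_min}")
        for name in self.selection:
            _check(name in _CRITERIA, f"selection criterion unknown: {name}")
        _check(len(self.selection) >= 1, "selection must be nonempty")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one threshold search; ``feasible`` is False when no
    candidate meets the constraints (a result, not an error)."""

    feasible: bool
    thresholds: Optional[DesrThresholds] = None
    oc: Optional[OperatingCharacteristics] = None


@dataclass(frozen=True)
class TableRow:
    n1: int
    n2: int
    result: SearchResult


def _selection_key(oc: OperatingCharacteristics, selection: tuple[str, ...]) -> tuple:
    return tuple(_CRITERIA[name](oc) for name in selection)


def search_thresholds(
    hyps: DualHypotheses,
    n1: int,
    n2: int,
    constraints: SearchConstraints,
    alt: Optional[AltMixture] = None,
    null: Optional[TrinomialRates] = None,
) -> SearchResult:
    """Exhaustive search for the preferred feasible DESR threshold set.

    Every returned design satisfies ``alpha <= alpha_max`` and
    ``power >= power_min`` when its operating characteristics are recomputed
    from scratch (they are computed by the same exact engine).

    Returns
    -------
    SearchResult
        ``feasible=False`` (with empty fields) when no candidate qualifies.
    """
    _check(n1 >= 1, f"n1 must be >= 1, got {n1}")
    _check(n2 >= 1, f"n2 must be >= 1, got {n2}")
    if null is None:
        null = TrinomialRates(hyps.r_nul, hyps.epd_nul)
    if alt is None:
        alt = AltMixture.borderline(hyps)

    configs = [null] + alt.rates
    weights = alt.weights
    pmf1 = [trinomial_pmf_matrix(n1, c) for c in configs]
    G = [_stage2_or_table(n2, c) for c in configs]

    kr = np.arange(n1 + 1)
    KR, KP = np.meshgrid(kr, kr, indexing="ij")
    lattice = KR + KP <= n1

    a_r_lo, a_r_hi = 1, n1 + n2  # per-candidate lower bound is s_r + 1
    a_p_vals = np.arange(-1, n1 + n2 + 1)

    best_key: Optional[tuple] = None
    best: Optional[tuple[DesrThresholds, OperatingCharacteristics]] = None

    for s_r in range(n1 + 1):
        for s_p in range(n1 + 2):
            stop = (KR <= s_r) & (KP >= s_p) & lattice
            cont = (~stop) & lattice
            kr_c = KR[cont]
            kp_c = KP[cont]

            pes = [float(m[stop].sum()) for m in pmf1]
            pes_nul = pes[0]
            pes_alt = float(np.dot(weights, pes[1:]))

            a_r_vals = np.arange(max(a_r_lo, s_r + 1), a_r_hi + 1)
            if a_r_vals.size == 0:
                continue
            X = np.clip(a_r_vals[:, None] - kr_c[None, :], 0, n2 + 1)
            Y = np.clip(a_p_vals[:, None] - kp_c[None, :], -1, n2) + 1

            rej = []
            for m, g in zip(pmf1, G):
                w_c = m[cont]
                # R[i, j] = sum_states w * G[a_r_i - k_r, a_p_j - k_p]
                R = np.einsum("s,ijs->ij", w_c, g[X[:, None, :], Y[None, :, :]])
                rej.append(R)
            alpha = rej[0]
            power = sum(w * r for w, r in zip(weights, rej[1:]))

            feas = (alpha <= constraints.alpha_max) & (power >= constraints.power_min)
            if not feas.any():
                continue

            ii, jj = np.nonzero(feas)
            for i, j in zip(ii, jj):
                oc = OperatingCharacteristics(
                    alpha=float(alpha[i, j]),
                    power=float(power[i, j]),
                    pes_nul=pes_nul,
                    en_nul=n1 + n2 * (1.0 - pes_nul),
                    pes_alt=pes_alt,
                    en_alt=n1 + n2 * (1.0 - pes_alt),
                )
                th = DesrThresholds(
                    n1=n1, n2=n2, s_r=s_r, s_p=s_p,
                    a_r=int(a_r_vals[i]), a_p=int(a_p_vals[j]),
                )
                # prefer larger criteria key; break ties on ascending bounds
                key = (
                    _selection_key(oc, constraints.selection),
                    (-th.s_r, -th.s_p, -th.a_r, -th.a_p),
                )
                if best_key is None or key > best_key:
                    best_key = key
                    best = (th, oc)

    if best is None:
        return SearchResult(feasible=False)
    return SearchResult(feasible=True, thresholds=best[0], oc=best[1])


def derive_table(
    hyps: DualHypotheses,
    n1: int,
    n2_list: list[int],
    constraints: SearchConstraints,
    alt: Optional[AltMixture] = None,
    null: Optional[TrinomialRates] = None,
) -> list[TableRow]:
    """Run :func:`search_thresholds` for each stage-II size in ``n2_list``.

    One row per ``n2``, in input order; infeasible searches are flagged in
    the row, never silently dropped.
    """
    _check(len(n2_list) > 0, "n2_list must be nonempty")
    return [
        TableRow(n1=n1, n2=n2, result=search_thresholds(hyps, n1, n2, constraints, alt=alt, null=null))
        for n2 in n2_list
    ]
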