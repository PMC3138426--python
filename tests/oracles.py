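"""Independent brute-force oracles for the exact probability engine.

Everything here is written as plain nested loops over the count lattices
with `math.comb`, deliberately sharing no code with the package's
enumeration (which works in log space with cumulative-sum tables), so
agreement is a genuine cross-check.
"""

from math import comb


def trinomial_pmf_bf(n: int, k_r: int, k_p: int, p_r: float, p_p: float) -> float:
    p_o = 1.0 - p_r - p_p
    return (
        comb(n, k_r)
        * comb(n - k_r, k_p)
        * p_r**k_r
        * p_p**k_p
        * p_o ** (n - k_r - k_p)
    )


def stage1_stop_bf(n1, s_r, s_p, p_r, p_p) -> float:
    """Direct double loop over the stage-1 lattice."""
    total = 0.0
    for k_r in range(n1 + 1):
        for k_p in range(n1 - k_r + 1):
            if k_r <= s_r and k_p >= s_p:
                total += trinomial_pmf_bf(n1, k_r, k_p, p_r, p_p)
    return total


def reject_bf(n1, n2, s_r, s_p, a_r, a_p, p_r, p_p) -> float:
    """Quadruple loop over the joint stage-1 x stage-2 lattice."""
    total = 0.0
    for k_r in range(n1 + 1):
        for k_p in range(n1 - k_r + 1):
            if k_r <= s_r and k_p >= s_p:
                continue
            w1 = trinomial_pmf_bf(n1, k_r, k_p, p_r, p_p)
            for j_r in range(n2 + 1):
                for j_p in range(n2 - j_r + 1):
                    if k_r + j_r >= a_r or k_p + j_p <= a_p:
                        total += w1 * trinomial_pmf_bf(n2, j_r, j_p, p_r, p_p)
    return total


def binom_pmf_bf(n: int, k: int, p: float) -> float:
    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def single_endpoint_reject_bf(n1, accept_bound, n2, final_reject_bound, p,
                              reject_bound_stage1=None):
    """Direct enumeration over stage-1 and stage-2 response counts.

    Returns (reject probability, early-stop probability).
    """
    reject = 0.0
    pes = 0.0
    for k in range(n1 + 1):
        w1 = binom_pmf_bf(n1, k, p)
        if k <= accept_bound:
            pes += w1
        elif reject_bound_stage1 is not None and k >= reject_bound_stage1:
            pes += w1
            reject += w1
        else:
            for j in range(n2 + 1):
                if k + j >= final_reject_bound:
                    reject += w1 * binom_pmf_bf(n2, j, p)
    return reject, pes


def gehan_upper75_bf(n1: int, r1: int, tol: float = 1e-12) -> float:
    """Exact one-sided upper 75% binomial confidence bound for r1/n1 by
    bisection on the lower-tail probability P(X <= r1 | n1, p) = 0.25."""
    if r1 == n1:
        return 1.0

    def lower_tail(p):
        return sum(binom_pmf_bf(n1, k, p) for k in range(r1 + 1))

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if lower_tail(mid) > 0.25:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
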