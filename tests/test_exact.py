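"""Exact operating-characteristics engine vs independent brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desr import (
    AltMixture,
    DesrThresholds,
    TrinomialRates,
    ValidationError,
    expected_sample_size,
    oc_for_design,
    prob_reject,
    prob_stage1_stop,
    single_endpoint_oc,
    trinomial_pmf,
)
from oracles import reject_bf, single_endpoint_reject_bf, stage1_stop_bf, trinomial_pmf_bf

# a spread of designs with n1, n2 <= 20 for oracle cross-checks
DESIGNS = [
    DesrThresholds(15, 15, 1, 8, 4, 14),   # published Fleming-sized bounds
    DesrThresholds(15, 15, 1, 6, 4, 11),
    DesrThresholds(14, 15, 1, 8, 4, 14),
    DesrThresholds(14, 4, 1, 8, 3, 9),
    DesrThresholds(10, 8, 2, 5, 4, 6),
    DesrThresholds(5, 5, 0, 3, 2, 2),
    DesrThresholds(20, 20, 3, 10, 7, 20),
    DesrThresholds(6, 1, 1, 7, 2, -1),     # degenerate: never stop, never reject on prog
]
RATES = [
    TrinomialRates(0.05, 0.6),
    TrinomialRates(0.2, 0.6),
    TrinomialRates(0.05, 0.4),
    TrinomialRates(0.3, 0.3),
]


class TestTrinomialPmf:
    def test_single_draw(self):
        assert trinomial_pmf(1, 1, 0, TrinomialRates(0.2, 0.3)) == pytest.approx(0.2)

    def test_two_draws(self):
        assert trinomial_pmf(2, 1, 1, TrinomialRates(0.2, 0.3)) == pytest.approx(0.12)

    def test_normalisation(self):
        rates = TrinomialRates(0.05, 0.6)
        total = sum(
            trinomial_pmf(15, kr, kp, rates)
            for kr in range(16)
            for kp in range(16 - kr)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_counts(self):
        with pytest.raises(ValidationError):
            trinomial_pmf(5, 3, 3, TrinomialRates(0.2, 0.3))

    @settings(max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 40),
        pr=st.floats(0.0, 1.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_normalisation_property(self, n, pr, frac):
        pp = (1.0 - pr) * frac
        rates = TrinomialRates(pr, pp)
        total = sum(
            trinomial_pmf(n, kr, kp, rates) for kr in range(n + 1) for kp in range(n - kr + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(
        n=st.integers(1, 20),
        kr=st.integers(0, 20),
        kp=st.integers(0, 20),
    )
    def test_matches_brute_force(self, n, kr, kp):
        if kr + kp > n:
            return
        rates = TrinomialRates(0.2, 0.3)
        assert trinomial_pmf(n, kr, kp, rates) == pytest.approx(
            trinomial_pmf_bf(n, kr, kp, 0.2, 0.3), abs=1e-13
        )


class TestStage1Stop:
    def test_certain_stop(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert prob_stage1_stop(th, TrinomialRates(0.0, 1.0)) == pytest.approx(1.0)

    def test_impossible_stop(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert prob_stage1_stop(th, TrinomialRates(1.0, 0.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("th", DESIGNS)
    @pytest.mark.parametrize("rates", RATES)
    def test_oracle_equivalence(self, th, rates):
        assert prob_stage1_stop(th, rates) == pytest.approx(
            stage1_stop_bf(th.n1, th.s_r, th.s_p, rates.p_r, rates.p_p), abs=1e-12
        )

    def test_monotone_in_rates(self):
        """Stage-1 stop probability falls as responses get likelier and
        rises as early progression gets likelier."""
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        grid = np.linspace(0.02, 0.3, 8)
        stops_r = [prob_stage1_stop(th, TrinomialRates(p, 0.5)) for p in grid]
        assert all(a >= b - 1e-12 for a, b in zip(stops_r, stops_r[1:]))
        grid_p = np.linspace(0.3, 0.65, 8)
        stops_p = [prob_stage1_stop(th, TrinomialRates(0.05, p)) for p in grid_p]
        assert all(a <= b + 1e-12 for a, b in zip(stops_p, stops_p[1:]))


class TestReject:
    def test_certain_rejection(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert prob_reject(th, TrinomialRates(1.0, 0.0)) == pytest.approx(1.0)

    def test_certain_stop_means_no_rejection(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert prob_reject(th, TrinomialRates(0.0, 1.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("th", DESIGNS)
    @pytest.mark.parametrize("rates", RATES)
    def test_oracle_equivalence(self, th, rates):
        assert prob_reject(th, rates) == pytest.approx(
            reject_bf(th.n1, th.n2, th.s_r, th.s_p, th.a_r, th.a_p, rates.p_r, rates.p_p),
            abs=1e-12,
        )


class TestExpectedSampleSize:
    def test_certain_stop_gives_n1(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert expected_sample_size(th, TrinomialRates(0.0, 1.0)) == pytest.approx(15.0)

    def test_certain_continue_gives_total(self):
        th = DesrThresholds(15, 15, 1, 8, 4, 14)
        assert expected_sample_size(th, TrinomialRates(1.0, 0.0)) == pytest.approx(30.0)

    def test_identity_with_stop_probability(self, th46, null46):
        pes = stage1_stop_bf(th46.n1, th46.s_r, th46.s_p, null46.p_r, null46.p_p)
        assert expected_sample_size(th46, null46) == pytest.approx(
            th46.n1 + th46.n2 * (1.0 - pes), abs=1e-12
        )


class TestOcForDesign:
    def test_degenerate_mixture_power(self, th46, hyps46):
        comp = TrinomialRates(hyps46.r_alt, hyps46.epd_nul)
        alt = AltMixture(((comp, 1.0), (TrinomialRates(hyps46.r_nul, hyps46.epd_alt), 0.0)))
        oc = oc_for_design(th46, hyps46, alt=alt)
        assert oc.power == pytest.approx(prob_reject(th46, comp), abs=1e-14)

    def test_en_pes_identity(self, th46, hyps46):
        oc = oc_for_design(th46, hyps46)
        assert oc.en_nul == pytest.approx(th46.n1 + th46.n2 * (1 - oc.pes_nul), abs=1e-12)
        assert oc.en_alt == pytest.approx(th46.n1 + th46.n2 * (1 - oc.pes_alt), abs=1e-12)

    def test_all_probabilities_in_unit_interval(self, th46, hyps46):
        oc = oc_for_design(th46, hyps46)
        for v in (oc.alpha, oc.power, oc.pes_nul, oc.pes_alt):
            assert 0.0 <= v <= 1.0
        assert th46.n1 <= oc.en_nul <= th46.n1 + th46.n2

    def test_invalid_mixture_weights(self):
        with pytest.raises(ValidationError):
            AltMixture(((TrinomialRates(0.2, 0.6), 0.7), (TrinomialRates(0.05, 0.4), 0.7)))


class TestSingleEndpoint:
    def test_zero_rate(self):
        oc = single_endpoint_oc(15, 0, 15, 4, p=0.0)
        assert oc.reject_prob == pytest.approx(0.0)
        assert oc.pes == pytest.approx(1.0)

    def test_certain_rate(self):
        oc = single_endpoint_oc(15, 0, 15, 4, p=1.0)
        assert oc.reject_prob == pytest.approx(1.0)

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    @pytest.mark.parametrize("erb", [None, 8])
    def test_oracle_equivalence(self, p, erb):
        oc = single_endpoint_oc(15, 0, 15, 4, p=p, reject_bound_stage1=erb)
        rej, pes = single_endpoint_reject_bf(15, 0, 15, 4, p, reject_bound_stage1=erb)
        assert oc.reject_prob == pytest.approx(rej, abs=1e-12)
        assert oc.pes == pytest.approx(pes, abs=1e-12)
        assert oc.en == pytest.approx(15 + 15 * (1 - pes), abs=1e-12)

    def test_inconsistent_bounds(self):
        with pytest.raises(ValidationError):
            single_endpoint_oc(15, 5, 15, 4, p=0.2)
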