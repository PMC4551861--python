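"""Epsilon-machine construction and exact information quantities."""

import math

import numpy as np
import pytest

import spikeinfo as si
from spikeinfo.discretize import DiscretizedRenewal
from spikeinfo.machine import binary_entropy

from conftest import enumerate_block_entropy, enumerate_word_distribution


def periodic_machine(period=4):
    """Noise-free clock firing every `period` bins."""
    F = np.zeros(period)
    F[-1] = 1.0
    w = np.concatenate([np.ones(period), [0.0]])
    disc = DiscretizedRenewal(dt=1.0, F=F, w=w, n_max=period, tail_mass=0.0,
                              tail_hazard=1.0)
    return si.build_renewal_machine(disc)


class TestTopologyDetection:
    def test_exponential_is_single_state(self):
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        assert m.topology == "poisson"
        assert m.n_states == 1
        assert m.emit1[0] == pytest.approx(1 - math.exp(-0.05), rel=1e-12)
        assert si.statistical_complexity(m) == pytest.approx(0.0, abs=1e-12)

    def test_refractory_poisson_chain_with_self_loop(self):
        # refractory period of 4 bins: 5 states, last one a self-loop
        m = si.build_renewal_machine(
            si.discretize_distribution(si.RefractoryPoisson(0.5, 0.4), 0.1))
        assert m.topology == "eventually_poisson"
        assert m.n_states == 5
        assert np.allclose(m.emit1[:4], 0.0)
        assert m.next0[4] == 4  # self-loop
        assert m.emit1[4] == pytest.approx(1 - math.exp(-0.05), rel=1e-9)

    def test_generic_chain_hazards(self, sig211):
        disc = si.discretize_distribution(sig211, 0.1)
        m = si.build_renewal_machine(disc)
        assert m.topology == "renewal"
        # transition probabilities are F(n)/w(n) by definition
        np.testing.assert_allclose(
            m.emit1[: disc.n_max], disc.F / disc.w[:-1], rtol=1e-12)
        assert np.all(m.next1 == 0)

    def test_stationary_matches_eigenvector(self, sig_machine_coarse):
        m = sig_machine_coarse
        T = m.transition_matrix()
        resid = m.stationary @ T - m.stationary
        assert np.max(np.abs(resid)) < 1e-12
        assert m.stationary.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_proportional_to_count_survival(self, sig211):
        disc = si.discretize_distribution(sig211, 0.2)
        m = si.build_renewal_machine(disc)
        # interior states: pi(n) / pi(0) = w(n)
        ratio = m.stationary[: disc.n_max] / m.stationary[0]
        np.testing.assert_allclose(ratio, disc.w[: disc.n_max], rtol=1e-8)


class TestScalarQuantities:
    def test_poisson_entropy_rate_is_binary_entropy(self):
        p = 1 - math.exp(-0.05)
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        assert si.entropy_rate(m) == pytest.approx(binary_entropy(p), rel=1e-12)

    def test_periodic_complexity_and_rate(self):
        m = periodic_machine(4)
        assert si.statistical_complexity(m) == pytest.approx(2.0, abs=1e-12)
        assert si.entropy_rate(m) == pytest.approx(0.0, abs=1e-12)

    def test_complexity_matches_direct_sum(self, sig_machine_coarse):
        pi = sig_machine_coarse.stationary
        direct = -sum(p * math.log2(p) for p in pi if p > 0)
        assert si.statistical_complexity(sig_machine_coarse) == pytest.approx(
            direct, abs=1e-10)

    def test_entropy_rate_matches_block_slope(self, sig_machine_coarse):
        prof = si.block_entropy_profile(sig_machine_coarse, 60)
        slope = prof[60] - prof[59]
        assert si.entropy_rate(sig_machine_coarse) == pytest.approx(
            slope, abs=1e-6)


class TestBlockEntropy:
    def test_single_symbol(self, sig_machine_coarse):
        m = sig_machine_coarse
        p1 = m.spike_probability()
        assert si.block_entropy(m, 1) == pytest.approx(binary_entropy(p1),
                                                       abs=1e-12)

    def test_poisson_is_iid(self):
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        prof = si.block_entropy_profile(m, 20)
        expected = np.arange(21) * binary_entropy(m.emit1[0])
        np.testing.assert_allclose(prof, expected, atol=1e-12)

    @pytest.mark.parametrize("L", [1, 2, 5, 9, 12])
    def test_matches_enumeration(self, sig_machine_coarse, L):
        assert si.block_entropy(sig_machine_coarse, L) == pytest.approx(
            enumerate_block_entropy(sig_machine_coarse, L), abs=1e-10)


class TestEntropyRateEstimators:
    def test_poisson_both_exact(self):
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        hb = binary_entropy(m.emit1[0]) / m.dt
        for L in (2, 5, 20):
            ratio, diff = si.entropy_rate_estimators(m, L)
            assert ratio == pytest.approx(hb, rel=1e-12)
            assert diff == pytest.approx(hb, rel=1e-12)

    def test_difference_converges_faster(self, sig_machine_coarse):
        m = sig_machine_coarse
        target = si.entropy_rate(m) / m.dt
        ratio, diff = si.entropy_rate_estimators(m, 40)
        assert abs(diff - target) < abs(ratio - target)

    def test_ratio_excess_identity(self, sig_machine_coarse):
        # H(dt,T)/T = h_mu/dt + E(T,dt)/T with E(T) = H(L) - L h_mu
        m = sig_machine_coarse
        L = 30
        prof = si.block_entropy_profile(m, L)
        ratio, _ = si.entropy_rate_estimators(m, L)
        E_T = prof[L] - L * si.entropy_rate(m)
        assert ratio == pytest.approx(
            si.entropy_rate(m) / m.dt + E_T / (L * m.dt), abs=1e-10)


class TestExcessEntropy:
    def test_poisson_zero(self):
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        assert si.excess_entropy_discrete(m, 20).extrapolated == pytest.approx(
            0.0, abs=1e-12)

    def test_periodic_equals_complexity(self):
        m = periodic_machine(4)
        res = si.excess_entropy_discrete(m, 10)
        assert res.extrapolated == pytest.approx(2.0, abs=1e-12)

    def test_matches_enumerated_mutual_information(self, sig_machine_coarse):
        m = sig_machine_coarse
        L = 6
        probs = enumerate_word_distribution(m, 2 * L)
        past, fut = {}, {}
        for w, p in probs.items():
            past[w[:L]] = past.get(w[:L], 0.0) + p
            fut[w[L:]] = fut.get(w[L:], 0.0) + p

        def H(d):
            return -sum(p * math.log2(p) for p in d.values())

        I_L = H(past) + H(fut) - H(probs)
        res = si.excess_entropy_discrete(m, L)
        assert res.profile[L - 1] == pytest.approx(I_L, abs=1e-10)

    def test_converges_to_continuum_for_gamma(self):
        # cross-module oracle: dt -> 0 extrapolation against the closed-form
        # continuum limit
        dist = si.Gamma(4.0, 0.5)
        target = si.excess_entropy_limit(dist)
        dts = [0.1, 0.05, 0.025]
        Es = []
        for dt in dts:
            m = si.build_renewal_machine(si.discretize_distribution(dist, dt))
            Es.append(si.excess_entropy_discrete(m, int(15 / dt)).extrapolated)
        E0 = float(np.polyval(np.polyfit(dts, Es, 2), 0.0))
        assert E0 == pytest.approx(target, rel=0.01)


class TestAnatomy:
    def test_poisson_anatomy(self):
        m = si.build_renewal_machine(
            si.discretize_distribution(si.Exponential(0.5), 0.1))
        an = si.anatomy_discrete(m, 30)
        assert an.b_mu == pytest.approx(0.0, abs=1e-10)
        assert an.r_mu == pytest.approx(an.h_mu, abs=1e-10)
        assert an.q_mu == pytest.approx(0.0, abs=1e-10)
        assert an.sigma_mu == pytest.approx(0.0, abs=1e-10)

    def test_periodic_anatomy(self):
        an = si.anatomy_discrete(periodic_machine(4), 12)
        assert an.h_mu == 0.0
        assert an.b_mu == pytest.approx(0.0, abs=1e-12)
        assert an.r_mu == pytest.approx(0.0, abs=1e-12)
        # present determined both ways: q = H[X_0]; sigma = H(future | X_0)
        # = (3/4) log2 3 for the period-4 clock (phase unknown among the
        # three silent slots when X_0 = 0)
        assert an.q_mu == pytest.approx(an.H0, abs=1e-12)
        assert an.sigma_mu == pytest.approx(0.75 * math.log2(3), abs=1e-10)

    def test_r_matches_enumeration(self, sig_machine_coarse):
        # H(X_0 | S_0, X_{1:K+1}) by explicit future-word enumeration
        import itertools

        m = sig_machine_coarse
        K = 8
        total = 0.0
        for s0, ps in enumerate(m.stationary):
            if ps == 0:
                continue
            joint, margf = {}, {}
            for word in itertools.product([0, 1], repeat=K + 1):
                pr, s = 1.0, s0
                for x in word:
                    e = m.emit1[s]
                    pr *= e if x == 1 else (1 - e)
                    if pr == 0:
                        break
                    s = m.next1[s] if x == 1 else m.next0[s]
                if pr > 0:
                    joint[word] = pr
                    margf[word[1:]] = margf.get(word[1:], 0.0) + pr
            total += ps * -sum(p * math.log2(p / margf[w[1:]])
                               for w, p in joint.items())
        from spikeinfo.machine import _renewal_future_conditional

        r_prof = _renewal_future_conditional(m, K)
        assert r_prof[K - 1] == pytest.approx(total, abs=1e-10)

    def test_identities_generic_machine(self, sig_machine_coarse):
        an = si.anatomy_discrete(sig_machine_coarse, 60)
        assert an.h_mu == pytest.approx(an.r_mu + an.b_mu, abs=1e-12)
        assert an.E == pytest.approx(an.b_mu + an.sigma_mu + an.q_mu,
                                     abs=1e-12)
        assert an.H0 == pytest.approx(an.q_mu + 2 * an.b_mu + an.r_mu,
                                      abs=1e-12)
        assert an.E <= an.C_mu


class TestCrypticity:
    def test_complexity_exceeds_excess_entropy_as_dt_shrinks(self, sig211):
        gaps = []
        for dt in (0.4, 0.2, 0.1):
            m = si.build_renewal_machine(si.discretize_distribution(sig211, dt))
            gap = si.statistical_complexity(m) - si.excess_entropy_discrete(
                m, int(25 / dt)).extrapolated
            gaps.append(gap)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_periodic_not_cryptic(self):
        m = periodic_machine(4)
        gap = si.statistical_complexity(m) - si.excess_entropy_discrete(
            m, 10).extrapolated
        assert gap == pytest.approx(0.0, abs=1e-10)


class TestSerialization:
    def test_json_round_numbers(self, sig_machine_coarse):
        import json

        doc = json.loads(sig_machine_coarse.to_json())
        assert doc["topology"] == "renewal"
        probs = [e["p"] for s in doc["states"] for e in s["edges"]]
        assert all(0 <= p <= 1 for p in probs)

    def test_dot_export(self):
        dot = periodic_machine(3).to_dot()
        assert dot.startswith("digraph")
        assert "|1" in dot and "|0" in dot

    def test_inconsistent_Fw_rejected(self):
        F = np.array([0.5, 0.5])
        w = np.array([1.0, 0.0, 0.0])
        disc = DiscretizedRenewal(dt=1.0, F=F, w=w, n_max=2, tail_mass=0.0,
                                  tail_hazard=0.5)
        with pytest.raises(ValueError):
            si.build_renewal_machine(disc)
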