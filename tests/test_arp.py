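"""Alternating renewal processes: composite formulas, machine, sampling."""

import math

import numpy as np
import pytest

import spikeinfo as si
from spikeinfo.arp import (
    ARPSpec,
    MixtureISI,
    arp_cmu_scaling,
    arp_excess_entropy_limit,
    arp_hmu_scaling,
    arp_machine,
    arp_sample,
    compare_to_noncomposite,
    modality_measures,
)
from spikeinfo.isi import LOG2E


@pytest.fixture(scope="module")
def exp_arp():
    return ARPSpec(si.Exponential(1.0), si.Exponential(0.4))


@pytest.fixture(scope="module")
def gamma_arp():
    return ARPSpec(si.Gamma(4.0, 0.5), si.Gamma(2.0, 1.0))


class TestSpec:
    def test_rates(self, exp_arp):
        assert exp_arp.mu1 == pytest.approx(1.0)
        assert exp_arp.mu2 == pytest.approx(0.4)
        assert exp_arp.mu == pytest.approx(2 * 0.4 / 1.4)

    def test_modality_entropy_bounds(self):
        eq = ARPSpec(si.Exponential(1.0), si.Exponential(1.0 + 1e-9))
        assert eq.modality_entropy == pytest.approx(1.0, abs=1e-6)
        skew = ARPSpec(si.Exponential(5.0), si.Exponential(0.1))
        assert 0 < skew.modality_entropy < 1

    def test_time_fractions(self, exp_arp):
        w1, w2 = exp_arp.time_fractions()
        assert w1 == pytest.approx(0.4 / 1.4)
        assert w1 + w2 == pytest.approx(1.0)


class TestModalityMeasures:
    def test_exponential_closed_forms(self):
        spec = ARPSpec(si.Exponential(0.5), si.Exponential(1.0))
        mm = modality_measures(spec, 1)
        # h = mu log2(e/mu); C = log2(e/mu); E = 0 for a memoryless modality
        assert mm.h == pytest.approx(0.5 * math.log2(math.e / 0.5), rel=1e-8)
        assert mm.C == pytest.approx(math.log2(math.e / 0.5), rel=1e-8)
        assert mm.E == 0.0

    def test_sig_modality_reuses_excess_entropy(self, sig211):
        spec = ARPSpec(sig211, si.Exponential(1.0))
        assert modality_measures(spec, 1).E == pytest.approx(
            si.excess_entropy_limit(sig211), abs=1e-9)

    def test_time_rescaled_modality_E_unchanged(self):
        a = ARPSpec(si.Gamma(4.0, 0.5), si.Exponential(1.0))
        b = ARPSpec(si.Gamma(4.0, 5.0), si.Exponential(0.1))
        assert modality_measures(a, 1).E == pytest.approx(
            modality_measures(b, 1).E, abs=1e-8)

    def test_bad_index(self, exp_arp):
        with pytest.raises(ValueError):
            modality_measures(exp_arp, 3)


class TestCompositeFormulas:
    def test_excess_entropy_exponential_modalities(self, exp_arp):
        # only the stored modality bit survives
        assert arp_excess_entropy_limit(exp_arp) == pytest.approx(
            exp_arp.modality_entropy, abs=1e-12)

    def test_equal_rate_contributes_one_bit(self):
        spec = ARPSpec(si.Gamma(4.0, 0.5), si.Gamma(2.0, 1.0))  # both mean 2
        E1 = modality_measures(spec, 1).E
        E2 = modality_measures(spec, 2).E
        assert arp_excess_entropy_limit(spec) == pytest.approx(
            1.0 + (E1 + E2) / 2, abs=1e-10)

    def test_hmu_symmetric_specialization(self):
        spec = ARPSpec(si.Gamma(4.0, 0.5), si.Gamma(2.0, 1.0))
        sc = arp_hmu_scaling(spec)
        h1 = modality_measures(spec, 1).h
        h2 = modality_measures(spec, 2).h
        assert sc.nondivergent_part == pytest.approx((h1 + h2) / 2, abs=1e-10)
        assert sc.divergence_coefficient == pytest.approx(spec.mu)

    def test_hmu_weights_are_time_fractions(self, exp_arp):
        sc = arp_hmu_scaling(exp_arp)
        h1 = modality_measures(exp_arp, 1).h
        h2 = modality_measures(exp_arp, 2).h
        w1, w2 = exp_arp.time_fractions()
        assert sc.nondivergent_part == pytest.approx(w1 * h1 + w2 * h2)

    def test_hmu_regression_selects_composite_rate(self, gamma_arp):
        sc = arp_hmu_scaling(gamma_arp, dts=np.array([0.08, 0.04, 0.02]))
        assert sc.empirical_coefficient == pytest.approx(gamma_arp.mu,
                                                         rel=0.08)
        assert sc.divergence_coefficient == pytest.approx(gamma_arp.mu)
        assert not sc.discrepancy

    def test_cmu_regression_selects_single_log_divergence(self, gamma_arp):
        sc = arp_cmu_scaling(gamma_arp, dts=np.array([0.08, 0.04, 0.02]))
        assert sc.empirical_coefficient == pytest.approx(1.0, abs=0.1)
        assert sc.divergence_coefficient == 1.0

    def test_E_invariant_under_joint_rescaling(self):
        a = ARPSpec(si.Gamma(4.0, 0.5), si.Exponential(1.0))
        b = ARPSpec(si.Gamma(4.0, 0.05), si.Exponential(10.0))
        assert arp_excess_entropy_limit(a) == pytest.approx(
            arp_excess_entropy_limit(b), abs=1e-8)


class TestMachine:
    def test_two_chain_construction(self):
        # same shape shifted by distinct refractory periods
        d1 = si.RefractoryPoisson(1.0, 1.0)
        d2 = si.RefractoryPoisson(1.0, 2.0)
        spec = ARPSpec(d1, d2)
        m = arp_machine(spec, 0.25)
        assert m.topology == "arp"
        K1, K2 = m.meta["chain_sizes"]
        # spikes from chain 1 land at the head of chain 2 and vice versa
        assert m.next1[0] == K1
        assert m.next1[K1] == 0

    def test_equal_modalities_rejected(self):
        d = si.discretize_distribution(si.Exponential(1.0), 0.1)
        with pytest.raises(ValueError, match="renewal"):
            si.build_arp_machine(d, d)

    def test_stationary_modality_marginal(self, exp_arp):
        # the chain weights converge to the time fractions as dt -> 0
        # (finite-dt weights carry an O(dt) correction)
        w1, _ = exp_arp.time_fractions()
        errs = []
        for dt in (0.04, 0.01):
            m = arp_machine(exp_arp, dt)
            K1, _ = m.meta["chain_sizes"]
            errs.append(abs(m.stationary[:K1].sum() - w1))
        assert errs[1] < errs[0] / 3
        assert errs[1] < 2e-3

    def test_stationary_matches_eigenvector(self, gamma_arp):
        m = arp_machine(gamma_arp, 0.1)
        resid = m.stationary @ m.transition_matrix() - m.stationary
        assert np.max(np.abs(resid)) < 1e-12

    def test_block_entropy_matches_enumeration(self, exp_arp):
        from conftest import enumerate_block_entropy

        m = arp_machine(exp_arp, 0.2)
        prof = si.block_entropy_profile(m, 10)
        for L in (1, 4, 8):
            assert prof[L] == pytest.approx(enumerate_block_entropy(m, L),
                                            abs=1e-9)

    def test_discrete_E_approaches_composite_limit(self, exp_arp):
        target = arp_excess_entropy_limit(exp_arp)
        m = arp_machine(exp_arp, 0.1)
        res = si.excess_entropy_discrete(m, 600)
        assert res.extrapolated == pytest.approx(target, rel=0.015)


class TestSampling:
    def test_alternating_labels(self, exp_arp):
        seq = arp_sample(exp_arp, 4, seed=0)
        assert seq.modalities.tolist() == [1, 2, 1, 2]
        seq2 = arp_sample(exp_arp, 4, seed=0, start="modality2")
        assert seq2.modalities.tolist() == [2, 1, 2, 1]

    def test_marginal_is_equal_weight_mixture(self, exp_arp):
        seq = arp_sample(exp_arp, 20000, seed=1)
        mix = MixtureISI(exp_arp.phi1, exp_arp.phi2)
        assert seq.intervals.mean() == pytest.approx(
            mix.moments().mean_isi, rel=0.03)

    def test_lag1_correlation_negative(self, exp_arp):
        v = arp_sample(exp_arp, 20000, seed=2).intervals
        r = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert r < -0.05

    def test_stationary_start_draws_modality(self, exp_arp):
        firsts = [arp_sample(exp_arp, 1, seed=s, start="stationary")
                  .modalities[0] for s in range(300)]
        frac1 = np.mean(np.array(firsts) == 1)
        w1, _ = exp_arp.time_fractions()
        assert frac1 == pytest.approx(w1, abs=0.1)


class TestNoncompositeComparison:
    def test_both_sides_computed(self, exp_arp):
        rec = compare_to_noncomposite(exp_arp)
        assert rec.E_arp == pytest.approx(exp_arp.modality_entropy)
        assert rec.E_renewal >= 0
        assert rec.renewal_E_smaller  # mixture forgets the modality
        # both divergence coefficients equal the composite firing rate
        assert rec.hmu_coef_renewal == pytest.approx(exp_arp.mu, rel=1e-9)
        assert rec.hmu_coef_leq_rate

    def test_cmu_coefficients_recorded(self, gamma_arp):
        rec = compare_to_noncomposite(gamma_arp)
        assert rec.cmu_coef_renewal == pytest.approx(1.0, abs=1e-6)
        assert rec.cmu_coef_arp == 1.0

    def test_mixture_distribution_consistent(self, exp_arp):
        mix = MixtureISI(exp_arp.phi1, exp_arp.phi2)
        t = 1.7
        assert mix.density(t) == pytest.approx(
            0.5 * (exp_arp.phi1.density(t) + exp_arp.phi2.density(t)))
        v = mix.sample(50000, seed=3).intervals
        assert v.mean() == pytest.approx(mix.moments().mean_isi, rel=0.03)
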