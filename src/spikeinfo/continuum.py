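"""Closed-form continuous-time limits of the information measures.

As the bin size dt shrinks, the binned renewal process shows a clean
separation into divergent and convergent parts:

* excess entropy  E(dt) -> int mu t phi log2(mu phi) - 2 int mu Phi log2(mu Phi)
* statistical complexity  C_mu(dt) ~ (mu int_0^T Phi) log2(1/dt) + const
  (T the eventually-Poisson horizon; for a generic ISI law the coefficient is
  mu int_0^inf Phi = 1 and the constant is the differential entropy of the
  time-since-last-spike density mu Phi)
* dt-entropy rate  h_mu(dt)/dt ~ mu log2(1/dt) - mu int phi log2 phi
* bound information rate  b_mu(dt)/dt -> -mu (int int phi phi' log2 phi(t+t')
  + log2 e - int phi log2 phi)

All integrals are in bits with times in ms; every quantity here is validated
against the discrete epsilon-machine route in the test suite.  The rescaled,
unit-free combinations used for cross-model comparison are:

  C*  = lim C_mu(dt) + log2(mu dt)      = -mu int Phi log2 Phi
  h*  = lim h_mu(dt)/(mu dt) + log2(mu dt) = log2 mu + H_diff[phi]
  E   = lim E(dt)
  b*  = lim b_mu(dt)/(mu dt)

which depend on the ISI law only through its shape (in particular its
coefficient of variation), not on the firing rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .isi import (
    LOG2E,
    Empirical,
    Exponential,
    Gamma,
    ISIDistribution,
    RefractoryPoisson,
    safe_log2,
    xlog2x,
)

QUAD_KW = dict(limit=500, epsabs=1e-10, epsrel=1e-10)


def _is_poisson(dist: ISIDistribution) -> bool:
    if isinstance(dist, Exponential):
        return True
    if isinstance(dist, RefractoryPoisson) and dist.refractory == 0:
        return True
    if isinstance(dist, Gamma) and dist.shape == 1.0:
        return True
    return False


def _peak_points(dist: ISIDistribution, lo: float, hi: float):
    """Breakpoints around the density peak, for sharply peaked laws."""
    m = dist.moments()
    sd = math.sqrt(max(m.variance, 1e-30))
    pts = [m.mean_isi + k * sd for k in (-6, -3, -1, 0, 1, 3, 6)]
    return [p for p in pts if lo < p < hi] or None


def _quad(dist, f, lo, hi):
    val, _ = integrate.quad(f, lo, hi, points=_peak_points(dist, lo, hi),
                            **QUAD_KW)
    return val


def excess_entropy_limit(dist: ISIDistribution) -> float:
    """lim_{dt->0} E(dt) in bits.

    Vanishes for the memoryless (Poisson) law; diverges logarithmically as
    the ISI law approaches a noise-free clock (C_V -> 0).
    """
    if _is_poisson(dist):
        return 0.0
    mu = dist.firing_rate
    a = dist.support_start
    hi = dist.upper_limit()
    # split off the log2(mu) parts using mu int t phi = 1 and mu int Phi = 1:
    # E = mu int t phi log2 phi - 2 mu int Phi log2 Phi - log2 mu
    # (Phi log2 Phi vanishes below the support start where Phi = 1)
    t1 = mu * _quad(dist, lambda t: t * float(xlog2x(dist.density(t))), a, hi)
    t2 = mu * _quad(dist, lambda t: float(xlog2x(dist.survival(t))), a, hi)
    return t1 - 2 * t2 - math.log2(mu)


def finite_time_excess_entropy(dist: ISIDistribution, T: float) -> float:
    """E(T): the predictable information in a length-T window (bits),
    nondecreasing in T and converging to excess_entropy_limit."""
    if T < 0:
        raise ValueError("T must be nonnegative")
    if T == 0.0 or _is_poisson(dist):
        return 0.0
    mu = dist.firing_rate
    m = dist.moments()
    a = dist.support_start
    hi = max(dist.upper_limit(), T * 1.001)

    surv_0T, _ = integrate.quad(lambda t: float(dist.survival(t)), 0.0, T,
                                points=_peak_points(dist, 0.0, T), **QUAD_KW)
    surv_T = max(m.mean_isi - surv_0T, 0.0)

    term1 = mu * surv_0T * math.log2(1.0 / mu)
    term2, _ = integrate.quad(
        lambda t: -2.0 * mu * float(xlog2x(dist.survival(t))), 0.0, T,
        points=_peak_points(dist, 0.0, T), **QUAD_KW)
    term3 = -float(xlog2x(mu * surv_T))
    term4 = 0.0
    if T > a:
        term4, _ = integrate.quad(
            lambda t: mu * t * float(xlog2x(dist.density(t))), a, T,
            points=_peak_points(dist, a, T), **QUAD_KW)
    lo5 = max(a, T)
    term5, _ = integrate.quad(
        lambda t: mu * float(xlog2x(dist.density(t))), lo5, hi,
        points=_peak_points(dist, lo5, hi), **QUAD_KW)
    term5 *= T
    return term1 + term2 + term3 + term4 + term5


@dataclass(frozen=True)
class ScalingResult:
    """Decomposition  quantity ~ divergence_coefficient * log2(1/dt) + nondivergent_part."""

    quantity: str
    divergence_coefficient: float
    nondivergent_part: float
    units: str = "bits"


def cmu_scaling(dist: ISIDistribution) -> ScalingResult:
    """Small-dt scaling of the statistical complexity.

    The divergence coefficient is the stationary probability that the time
    since the last spike is below the eventually-Poisson horizon (1 for a
    generic law, 0 for Poisson); the nondivergent part is the differential
    entropy of the time-since-last-spike density mu Phi (plus the tail term
    for eventually-Poisson laws).
    """
    mu = dist.firing_rate
    if _is_poisson(dist):
        return ScalingResult("C_mu", 0.0, 0.0)
    if isinstance(dist, RefractoryPoisson):
        T, lam = dist.refractory, dist.rate
        coef = mu * T
        # the integral runs over [0, T) where Phi = 1; beyond the horizon the
        # whole exponential stretch collapses into the lumped tail state
        # carrying stationary mass mu int_T^inf Phi = mu/lam
        part1 = -T * mu * math.log2(mu)
        part2 = -float(xlog2x(mu / lam))
        return ScalingResult("C_mu", coef, part1 + part2)
    a = dist.support_start
    hi = dist.upper_limit()
    coef, _ = integrate.quad(lambda t: mu * float(dist.survival(t)), 0, hi,
                             points=_peak_points(dist, 0, hi), **QUAD_KW)
    nondiv = -mu * a * math.log2(mu)  # Phi = 1 below the support start
    nondiv += _quad(dist,
                    lambda t: -mu * float(xlog2x(dist.survival(t)))
                    - mu * float(dist.survival(t)) * math.log2(mu), a, hi)
    return ScalingResult("C_mu", coef, nondiv)


def hmu_scaling(dist: ISIDistribution) -> ScalingResult:
    """Small-dt scaling of the dt-entropy rate h_mu(dt)/dt (bits/ms):
    coefficient mu, nondivergent part mu * differential entropy of phi."""
    mu = dist.firing_rate
    return ScalingResult("h_mu/dt", mu, mu * dist.differential_entropy(),
                         units="bits/ms")


def bmu_rate_limit(dist: ISIDistribution) -> float:
    """lim_{dt->0} b_mu(dt)/dt in bits/ms: the rate at which spontaneously
    generated information is actively stored.  Zero for Poisson."""
    if _is_poisson(dist):
        return 0.0
    mu = dist.firing_rate
    cross = dist.cross_term_integral()
    h_diff = dist.differential_entropy()
    return -mu * (cross + LOG2E + h_diff)


@dataclass(frozen=True)
class RescaledQuantities:
    """The four unit-free quantities used for cross-model comparison.
    ``bmu_rescaled`` is None when the C_V floor forbids a reliable cross-term
    (small-C_V empirical laws)."""

    cmu_rescaled: float
    hmu_rescaled: float
    E: float
    bmu_rescaled: float | None
    cv: float
    firing_rate: float

    def as_tuple(self):
        return (self.cmu_rescaled, self.hmu_rescaled, self.E,
                self.bmu_rescaled)


def rescaled_universal_quantities(dist: ISIDistribution,
                                  compute_bmu: bool = True) -> RescaledQuantities:
    """lim C_mu(dt)+log2(mu dt), lim h_mu(dt)/(mu dt)+log2(mu dt), lim E(dt),
    lim b_mu(dt)/(mu dt) - all dimensionless and invariant under time
    rescaling.  The exactly-Poisson law reports (0, log2 e, 0, 0), its
    single-state machine values."""
    m = dist.moments()
    mu = m.firing_rate
    if _is_poisson(dist):
        return RescaledQuantities(0.0, LOG2E, 0.0, 0.0, m.cv, mu)
    if isinstance(dist, Empirical):
        return _rescaled_empirical(dist, compute_bmu=compute_bmu)
    a, hi = dist.support_start, dist.upper_limit()
    cmu_r = -mu * _quad(dist, lambda t: float(xlog2x(dist.survival(t))), a, hi)
    hmu_r = math.log2(mu) + dist.differential_entropy()
    E = excess_entropy_limit(dist)
    bmu_r = bmu_rate_limit(dist) / mu if compute_bmu else None
    return RescaledQuantities(cmu_r, hmu_r, E, bmu_r, m.cv, mu)


def _rescaled_empirical(dist: Empirical, compute_bmu: bool = True,
                        seed: int = 0) -> RescaledQuantities:
    """Plug-in estimates of the rescaled quantities from samples: exact
    step-function survival integrals, histogram density for the entropy and
    cross terms."""
    m = dist.moments()
    mu = m.firing_rate
    S = dist.survival_integral_log()  # -int Phi_hat log2 Phi_hat dt
    cmu_r = mu * S
    h_diff = dist.differential_entropy()
    hmu_r = math.log2(mu) + h_diff
    # E term 1: mu E[T log2(mu phi(T))] via the histogram density
    dens = np.maximum(dist.density(dist.samples), 1e-300)
    t1 = mu * float(np.mean(dist.samples * np.log2(mu * dens)))
    E = t1 + 2 * mu * S - 2 * math.log2(mu)
    bmu_r = None
    if compute_bmu and m.cv >= dist.cv_floor:
        cross = dist.cross_term_integral(seed=seed)
        bmu_r = -(cross + LOG2E + h_diff)
    return RescaledQuantities(cmu_r, hmu_r, E, bmu_r, m.cv, mu)


def rescaled_with_errors(samples: np.ndarray, n_blocks: int = 4,
                         seed: int = 0, compute_bmu: bool = True):
    """Rescaled quantities from an ISI sample plus block-subsample standard
    errors: (values, errors) as two RescaledQuantities-like tuples."""
    samples = np.asarray(samples, float)
    full = _rescaled_empirical(Empirical(samples), compute_bmu=compute_bmu,
                               seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(samples.size)
    blocks = np.array_split(perm, n_blocks)
    vals = []
    for blk in blocks:
        try:
            r = _rescaled_empirical(Empirical(samples[blk]),
                                    compute_bmu=compute_bmu, seed=seed + 1)
            vals.append([r.cmu_rescaled, r.hmu_rescaled, r.E,
                         np.nan if r.bmu_rescaled is None else r.bmu_rescaled])
        except ValueError:
            vals.append([np.nan] * 4)
    arr = np.asarray(vals, float)
    with np.errstate(invalid="ignore"):
        se = np.nanstd(arr, axis=0, ddof=1) / math.sqrt(n_blocks)
    return full, se


def divergence_regression(values: np.ndarray, dts: np.ndarray):
    """Fit  value = coef * log2(1/dt) + const  over a dt grid; returns
    (coef, const).  Used to validate the analytic divergence coefficients
    against the discrete-machine route."""
    x = np.log2(1.0 / np.asarray(dts, float))
    coef, const = np.polyfit(x, np.asarray(values, float), 1)
    return float(coef), float(const)
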