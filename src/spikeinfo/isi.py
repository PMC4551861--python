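"""Interspike-interval (ISI) distributions and their derived quantities.

A spike train whose ISIs are independent draws from a common law phi(t) is a
renewal process; everything downstream (discretization, epsilon-machines,
continuum limits) is driven by the density phi, the survival function
Phi(t) = P(ISI > t), the mean firing rate mu = 1/E[ISI] and the coefficient
of variation C_V = sd/mean.  The canonical time unit is milliseconds; unit
conversions happen only at I/O boundaries.

Analytic families
-----------------
exponential(rate)                    memoryless (Poisson neuron)
refractory_poisson(rate, refractory) exponential shifted by a dead time
shifted_inverse_gaussian(tau, b, lam) first-passage law of a drift-diffusion
                                     neuron with hard refractory period tau:
                                     tau + InverseGaussian(mean 1/b, shape lam)
gamma(shape, scale)                  gamma-distributed ISIs
empirical                            plug-in distribution built from samples
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import integrate
from scipy import stats

LOG2E = math.log2(math.e)

#: absolute tolerance for adaptive quadrature
QUAD_ABS_TOL = 1e-10
#: survival level below which infinite upper limits are truncated
SURVIVAL_TRUNC = 1e-12
#: floor inside log2 to honour the 0 log 0 = 0 convention
_LOG_FLOOR = 1e-300
#: default C_V floor below which the empirical cross-term is refused
EMPIRICAL_CV_FLOOR = 0.25


def xlog2x(p: np.ndarray | float) -> np.ndarray | float:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = p * np.log2(np.maximum(p, _LOG_FLOOR))
    return out if out.ndim else float(out)


def safe_log2(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    out = np.log2(np.maximum(p, _LOG_FLOOR))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Moments:
    """First two moments of an ISI law (times in ms)."""

    mean_isi: float
    firing_rate: float
    cv: float
    variance: float
    finite_variance: bool = True


@dataclass
class ISISequence:
    """An ordered sequence of interspike intervals (ms).

    ``origin`` records whether the first interval is a complete interval
    ("full") or potentially censored; all simulators here emit full intervals.
    ``modalities`` is used by alternating renewal processes (1-based labels).
    """

    intervals: np.ndarray
    origin: str = "full"
    modalities: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size < 1:
            raise ValueError("need at least one interval")
        if np.any(self.intervals <= 0):
            raise ValueError("all intervals must be strictly positive")

    def __len__(self) -> int:
        return self.intervals.size

    def spike_times(self, t0: float = 0.0) -> np.ndarray:
        """Event times with the first spike at t0 + first interval."""
        return t0 + np.cumsum(self.intervals)


class ISIDistribution:
    """Base class: an ISI law with density, survival, moments and a sampler."""

    family: str = "abstract"
    support_start: float = 0.0

    # -- core surface -----------------------------------------------------
    def density(self, t):
        """phi(t), in 1/ms; zero below the support start, error for t < 0."""
        raise NotImplementedError

    def survival(self, t):
        """Phi(t) = P(ISI > t)."""
        raise NotImplementedError

    def moments(self) -> Moments:
        raise NotImplementedError

    def sample(self, n: int, seed=None) -> ISISequence:
        """n independent draws; reproducible for a given seed."""
        raise NotImplementedError

    # -- shared helpers ---------------------------------------------------
    def _check_t(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        return t

    def upper_limit(self) -> float:
        """A time beyond which the survival mass is below SURVIVAL_TRUNC."""
        m = self.moments()
        hi = m.mean_isi + 10 * math.sqrt(max(m.variance, 1e-30))
        while self.survival(hi) > SURVIVAL_TRUNC:
            hi *= 1.5
            if hi > 1e12:  # pragma: no cover - diagnostic guard
                raise RuntimeError("survival does not decay; cannot truncate")
        return hi

    def _quad(self, f: Callable, a: float, b: float, points=None) -> float:
        val, _ = integrate.quad(
            f, a, b, limit=500, epsabs=QUAD_ABS_TOL, epsrel=1e-10, points=points
        )
        return val

    def differential_entropy(self) -> float:
        """-int phi log2 phi dt, in bits (quadrature fallback)."""
        hi = self.upper_limit()
        a = self.support_start
        f = lambda t: -float(xlog2x(self.density(t)))
        return self._quad(f, a, hi)

    def plogp_integral(self) -> float:
        """int phi(t) log2 phi(t) dt = -differential_entropy()."""
        return -self.differential_entropy()

    def cross_term_integral(self) -> float:
        """int int phi(t) phi(t') log2 phi(t+t') dt dt' by nested quadrature."""
        hi = self.upper_limit()
        a = self.support_start

        def inner(t):
            g = lambda tp: self.density(tp) * safe_log2(self.density(t + tp))
            return self._quad(g, a, hi)

        return self._quad(lambda t: self.density(t) * inner(t), a, hi)

    # convenience used throughout the continuum-limit formulas
    @property
    def firing_rate(self) -> float:
        return self.moments().firing_rate


class Exponential(ISIDistribution):
    """Memoryless ISI law: a Poisson neuron with firing rate ``rate`` (1/ms)."""

    family = "exponential"

    def __init__(self, rate: float):
        if rate <= 0:
            raise ValueError("rate must be positive")
        self.rate = float(rate)
        self._dist = stats.expon(scale=1.0 / self.rate)

    def density(self, t):
        t = self._check_t(t)
        out = self._dist.pdf(t)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        out = self._dist.sf(t)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> Moments:
        m = 1.0 / self.rate
        return Moments(m, self.rate, 1.0, m * m)

    def sample(self, n, seed=None) -> ISISequence:
        rng = np.random.default_rng(seed)
        return ISISequence(rng.exponential(1.0 / self.rate, size=int(n)),
                           meta={"family": self.family, "seed": seed})

    def differential_entropy(self) -> float:
        return math.log2(math.e / self.rate)

    def cross_term_integral(self) -> float:
        # t + t' ~ Gamma(2, 1/rate): E[log2 phi] = log2 rate - rate E[t+t'] log2 e
        return math.log2(self.rate) - 2 * LOG2E


class RefractoryPoisson(ISIDistribution):
    """Poisson neuron with a hard refractory (dead) time before the
    exponential stage: phi(t) = rate * exp(-rate (t - refractory)) above
    the refractory period.  The canonical eventually-Poisson process."""

    family = "refractory_poisson"

    def __init__(self, rate: float, refractory: float):
        if rate <= 0 or refractory < 0:
            raise ValueError("rate must be positive, refractory nonnegative")
        self.rate = float(rate)
        self.refractory = float(refractory)
        self.support_start = self.refractory

    def density(self, t):
        t = self._check_t(t)
        x = t - self.refractory
        out = np.where(x >= 0, self.rate * np.exp(-self.rate * np.maximum(x, 0.0)), 0.0)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        x = t - self.refractory
        out = np.where(x > 0, np.exp(-self.rate * np.maximum(x, 0.0)), 1.0)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> Moments:
        mean = self.refractory + 1.0 / self.rate
        var = 1.0 / self.rate**2
        return Moments(mean, 1.0 / mean, math.sqrt(var) / mean, var)

    def sample(self, n, seed=None) -> ISISequence:
        rng = np.random.default_rng(seed)
        draws = self.refractory + rng.exponential(1.0 / self.rate, size=int(n))
        return ISISequence(draws, meta={"family": self.family, "seed": seed})

    def differential_entropy(self) -> float:
        # a time shift leaves the differential entropy unchanged
        return math.log2(math.e / self.rate)

    def cross_term_integral(self) -> float:
        # t + t' = 2 refractory + Gamma(2, 1/rate); phi(t+t') is evaluated at
        # least one refractory period into the exponential stage.
        lam, tau = self.rate, self.refractory
        return math.log2(lam) - LOG2E * lam * (tau + 2.0 / lam)


class ShiftedInverseGaussian(ISIDistribution):
    """First-passage ISI law of a noisy (non-leaky) integrate-and-fire neuron.

    tau + InverseGaussian(mean 1/b, shape lam), where tau is the hard
    refractory period, b the drift of the membrane voltage and lam = 1/D the
    reciprocal noise intensity.  The mean firing rate entering the continuum
    formulas is the reciprocal of the FULL mean ISI, 1/(tau + 1/b).
    """

    family = "shifted_inverse_gaussian"

    def __init__(self, tau: float, b: float, lam: float):
        if tau < 0 or b <= 0 or lam <= 0:
            raise ValueError("need tau >= 0, b > 0, lam > 0")
        self.tau, self.b, self.lam = float(tau), float(b), float(lam)
        self.support_start = self.tau
        m = 1.0 / self.b
        # scipy: IG(mean m, shape lam) == invgauss(mu=m/lam, scale=lam)
        self._ig = stats.invgauss(m / self.lam, scale=self.lam)

    def density(self, t):
        t = self._check_t(t)
        x = np.atleast_1d(t - self.tau)
        out = np.zeros_like(x)
        pos = x > 0
        if pos.any():
            out[pos] = self._ig.pdf(x[pos])
        return float(out[0]) if np.ndim(t) == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        x = t - self.tau
        out = np.where(x > 0, self._ig.sf(np.maximum(x, 0.0)), 1.0)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> Moments:
        m_ig = 1.0 / self.b
        mean = self.tau + m_ig
        var = m_ig**3 / self.lam
        return Moments(mean, 1.0 / mean, math.sqrt(var) / mean, var)

    def sample(self, n, seed=None) -> ISISequence:
        rng = np.random.default_rng(seed)
        draws = self.tau + self._ig.rvs(size=int(n), random_state=rng)
        return ISISequence(draws, meta={"family": self.family, "seed": seed})

    def differential_entropy(self) -> float:
        hi = self.upper_limit()
        f = lambda t: -float(xlog2x(self.density(t)))
        return self._quad(f, self.tau, hi)

    def cross_term_integral(self) -> float:
        # The sum of two iid IG(m, lam) with common lam/m^2 is
        # IG(2m, 4 lam); reduce the double integral to one dimension.
        m = 1.0 / self.b
        c = self.lam / m**2
        msum, lsum = 2 * m, 4 * self.lam
        dsum = stats.invgauss(msum / lsum, scale=lsum)
        hi = 2 * self.tau + dsum.isf(SURVIVAL_TRUNC)

        def f(s):
            return dsum.pdf(max(s - 2 * self.tau, 1e-300)) * safe_log2(
                self.density(s)
            )

        return self._quad(f, 2 * self.tau, hi)


class Gamma(ISIDistribution):
    """Gamma-distributed ISIs; C_V = 1/sqrt(shape); shape 1 is Poisson."""

    family = "gamma"

    def __init__(self, shape: float, scale: float = 1.0):
        if shape <= 0 or scale <= 0:
            raise ValueError("shape and scale must be positive")
        self.shape, self.scale = float(shape), float(scale)
        self._dist = stats.gamma(self.shape, scale=self.scale)

    def density(self, t):
        t = self._check_t(t)
        out = self._dist.pdf(t)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        out = self._dist.sf(t)
        return float(out) if out.ndim == 0 else out

    def moments(self) -> Moments:
        mean = self.shape * self.scale
        var = self.shape * self.scale**2
        return Moments(mean, 1.0 / mean, 1.0 / math.sqrt(self.shape), var)

    def sample(self, n, seed=None) -> ISISequence:
        rng = np.random.default_rng(seed)
        return ISISequence(rng.gamma(self.shape, self.scale, size=int(n)),
                           meta={"family": self.family, "seed": seed})

    def differential_entropy(self) -> float:
        k, th = self.shape, self.scale
        nats = k + math.lgamma(k) + (1 - k) * _digamma(k) + math.log(th)
        return nats * LOG2E

    def cross_term_integral(self) -> float:
        # t + t' ~ Gamma(2k, scale); E[log phi(S)] has a closed form.
        k, th = self.shape, self.scale
        e_log_s = _digamma(2 * k) + math.log(th)  # E[ln S]
        e_s = 2 * k * th
        nats = (k - 1) * e_log_s - e_s / th - math.lgamma(k) - k * math.log(th)
        return nats * LOG2E


def _digamma(x: float) -> float:
    from scipy.special import digamma

    return float(digamma(x))


class Empirical(ISIDistribution):
    """Plug-in ISI distribution built from observed intervals.

    The survival function is the exact empirical step function; the density is
    a histogram estimate (Freedman-Diaconis bins by default) or a Gaussian
    kernel estimate (``density_estimator="kde"``).  Moments are plug-in.
    """

    family = "empirical"

    def __init__(self, samples, density_estimator: str = "histogram",
                 cv_floor: float = EMPIRICAL_CV_FLOOR):
        samples = np.asarray(samples, dtype=float)
        if samples.size < 2:
            raise ValueError("need at least two samples")
        if np.any(samples <= 0):
            raise ValueError("intervals must be positive")
        self.samples = np.sort(samples)
        self.n = samples.size
        self.cv_floor = cv_floor
        self.density_estimator = density_estimator
        self.support_start = 0.0
        if density_estimator == "kde" and self.samples.std() > 0:
            self._kde = stats.gaussian_kde(self.samples)
        else:
            self._kde = None
        if self.samples.std() > 0:
            counts, edges = np.histogram(self.samples, bins="fd")
        else:
            counts, edges = np.histogram(self.samples, bins=1)
        widths = np.diff(edges)
        self._edges = edges
        self._dens = counts / (self.n * widths)

    def density(self, t):
        t = self._check_t(t)
        if self._kde is not None:
            out = self._kde(np.atleast_1d(t))
            return float(out[0]) if np.ndim(t) == 0 else out
        idx = np.clip(np.searchsorted(self._edges, t, side="right") - 1, 0,
                      len(self._dens) - 1)
        inside = (t >= self._edges[0]) & (t <= self._edges[-1])
        out = np.where(inside, self._dens[idx], 0.0)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = self._check_t(t)
        out = 1.0 - np.searchsorted(self.samples, t, side="right") / self.n
        return float(out) if np.ndim(out) == 0 else out

    def moments(self) -> Moments:
        mean = float(self.samples.mean())
        var = float(self.samples.var())
        cv = math.sqrt(var) / mean if mean > 0 else math.nan
        return Moments(mean, 1.0 / mean, cv, var)

    def sample(self, n, seed=None) -> ISISequence:
        rng = np.random.default_rng(seed)
        return ISISequence(rng.choice(self.samples, size=int(n), replace=True),
                           meta={"family": self.family, "seed": seed})

    def differential_entropy(self) -> float:
        """Histogram plug-in estimate of -int phi log2 phi."""
        mask = self._dens > 0
        widths = np.diff(self._edges)[mask]
        d = self._dens[mask]
        return float(-np.sum(d * widths * np.log2(d)))

    def survival_integral_log(self) -> float:
        """Exact -int Phi_hat log2 Phi_hat dt for the empirical step survival."""
        s = self.samples
        surv = 1.0 - np.arange(1, self.n) / self.n  # value on (s_i, s_{i+1})
        gaps = np.diff(s)
        return float(-np.sum(gaps * xlog2x(surv)))

    def cross_term_integral(self, seed=0, n_pairs: int | None = None) -> float:
        """Monte-Carlo plug-in for the double integral, using resampled pairs
        and the estimated density.  Refused when C_V is below the floor, where
        the log-density of the sum cannot be estimated reliably."""
        m = self.moments()
        if m.cv < self.cv_floor:
            raise ValueError(
                f"empirical cross term refused: cv={m.cv:.3f} below floor "
                f"{self.cv_floor}")
        rng = np.random.default_rng(seed)
        n_pairs = n_pairs or min(10 * self.n, 10**6)
        a = rng.choice(self.samples, size=n_pairs, replace=True)
        b = rng.choice(self.samples, size=n_pairs, replace=True)
        dens = self.density(a + b)
        dens = np.maximum(dens, 1.0 / (self.n * (self.samples[-1] - self.samples[0] + 1e-12)))
        return float(np.mean(np.log2(dens)))


_FAMILIES = {
    "exponential": Exponential,
    "refractory_poisson": RefractoryPoisson,
    "shifted_inverse_gaussian": ShiftedInverseGaussian,
    "gamma": Gamma,
}


def isi_distribution(family: str, **params) -> ISIDistribution:
    """Factory from a config-style spec: family name + named parameters."""
    if family == "empirical":
        return Empirical(**params)
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown ISI family {family!r}; "
                         f"choose from {sorted(_FAMILIES) + ['empirical']}")
    return cls(**params)


def empirical_from_isis(samples: ISISequence | Sequence[float],
                        density_estimator: str = "histogram") -> Empirical:
    """Build the plug-in empirical distribution from an ISI sequence."""
    if isinstance(samples, ISISequence):
        samples = samples.intervals
    return Empirical(samples, density_estimator=density_estimator)


# ---------------------------------------------------------------------------
# plain-text I/O: one positive decimal per line, or CSV with an isi_ms column
# ---------------------------------------------------------------------------

def load_isis(path) -> ISISequence:
    path = Path(path)
    text = path.read_text().strip()
    first = text.splitlines()[0]
    if "," in first or "isi_ms" in first:
        import pandas as pd

        df = pd.read_csv(path)
        if "isi_ms" not in df.columns:
            raise ValueError("CSV ISI files must have an 'isi_ms' column")
        vals = df["isi_ms"].to_numpy(dtype=float)
    else:
        vals = np.array([float(x) for x in text.split()], dtype=float)
    return ISISequence(vals, meta={"path": str(path)})


def save_isis(seq: ISISequence, path) -> None:
    Path(path).write_text("\n".join(f"{x:.9g}" for x in seq.intervals) + "\n")
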