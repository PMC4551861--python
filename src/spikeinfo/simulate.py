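"""Stochastic integrate-and-fire simulators producing renewal ISI sequences.

Four spike-train generators share one surface:

NIF   non-leaky drift-diffusion neuron dV/dt = b + sqrt(D) eta(t); spike at
      V = 1, reset to 0, then a hard refractory period tau.  Its ISI law is
      exactly tau + InverseGaussian(mean 1/b, shape 1/D), so an exact sampler
      is available alongside the Euler-Maruyama route.
LIF   leaky neuron dV/dt = b - V + a eta(t); spike at V = 1, reset to 0.
QIF   quadratic neuron dV/dt = b + V^2 + a eta(t); spike at V = 100,
      reset to -100 (finite stand-ins for +/- infinity).
GISI  gamma-distributed ISIs drawn directly (no membrane dynamics).

Because each ISI restarts from a fixed reset voltage, the intervals are iid:
the integrator therefore runs one independent "particle" per requested ISI,
vectorized across particles.  Threshold crossings are detected at the end of
an integration step and the spike time is assigned to that step's end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .isi import Gamma, ISISequence, ShiftedInverseGaussian

#: default integration step = DEFAULT_STEP_FRACTION * (estimated mean ISI),
#: never above STEP_CAP_MS (first-passage bias of Euler-Maruyama ~ sqrt(step))
DEFAULT_STEP_FRACTION = 1e-3
STEP_CAP_MS = 1e-3

#: give up if a particle has not fired after this many mean-ISI estimates
MAX_TIME_FACTOR = 1e3

THRESHOLDS = {"NIF": (1.0, 0.0), "LIF": (1.0, 0.0), "QIF": (100.0, -100.0)}


@dataclass(frozen=True)
class NeuronModel:
    """Parameters of one spike-train generator.

    kind one of NIF/LIF/QIF/GISI; b is the drift, ``noise`` the white-noise
    amplitude (a for LIF/QIF, D for NIF), tau the NIF refractory period (ms),
    shape/scale the GISI gamma parameters.
    """

    kind: str
    b: float = 1.0
    noise: float = 0.0
    tau: float = 0.0
    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("NIF", "LIF", "QIF", "GISI"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if self.noise < 0 or self.tau < 0:
            raise ValueError("noise amplitude and refractory must be >= 0")

    def isi_distribution(self):
        """Analytic ISI law, where one exists (NIF and GISI)."""
        if self.kind == "NIF":
            if self.noise == 0:
                raise ValueError("noiseless NIF has a degenerate (delta) ISI law")
            return ShiftedInverseGaussian(self.tau, self.b, 1.0 / self.noise)
        if self.kind == "GISI":
            return Gamma(self.shape, self.scale)
        raise ValueError(f"{self.kind} has no closed-form ISI distribution")


def _drift(kind: str, b: float):
    if kind == "NIF":
        return lambda v: b
    if kind == "LIF":
        return lambda v: b - v
    if kind == "QIF":
        return lambda v: b + v * v
    raise ValueError(kind)


def _mean_isi_guess(model: NeuronModel) -> float:
    """Rough deterministic mean-ISI scale used to pick the step size."""
    k, b = model.kind, model.b
    if k == "NIF":
        return model.tau + 1.0 / b
    if k == "LIF":
        if b > 1:
            return math.log(b / (b - 1.0))
        # subthreshold: noise-driven escape; use the distance/noise scale
        return max(1.0, (1.0 - b) / max(model.noise, 1e-6)) ** 2
    if k == "QIF":
        sb = math.sqrt(max(b, 1e-6))
        return 2.0 * math.atan(100.0 / sb) / sb
    return model.shape * model.scale


def simulate_isis(model: NeuronModel, n: int, seed=None,
                  sim_step: float | None = None) -> ISISequence:
    """Draw n ISIs by Euler-Maruyama integration of the membrane SDE.

    GISI draws directly from the gamma law.  For noiseless LIF, b > 1 is
    required (otherwise the voltage never reaches threshold).  Raises if any
    particle fails to spike within MAX_TIME_FACTOR mean-ISI estimates.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if model.kind == "GISI":
        draws = rng.gamma(model.shape, model.scale, size=n)
        return ISISequence(draws, meta={"model": model, "seed": seed})
    if model.kind == "LIF" and model.noise == 0 and model.b <= 1:
        raise ValueError("noiseless LIF with b <= 1 never fires")

    mean_guess = _mean_isi_guess(model)
    dt = sim_step if sim_step is not None else min(
        DEFAULT_STEP_FRACTION * mean_guess, STEP_CAP_MS)
    thresh, reset = THRESHOLDS[model.kind]
    drift = _drift(model.kind, model.b)
    # NIF's noise parameter is the intensity D (variance per unit time);
    # LIF/QIF's is the amplitude a multiplying white noise directly
    sigma = (math.sqrt(model.noise * dt) if model.kind == "NIF"
             else model.noise * math.sqrt(dt))
    max_steps = int(MAX_TIME_FACTOR * mean_guess / dt)

    v = np.full(n, reset, dtype=float)
    steps = np.zeros(n, dtype=np.int64)
    alive = np.arange(n)
    taken = 0
    while alive.size:
        taken += 1
        if taken > max_steps:
            raise RuntimeError(
                f"{alive.size} trajectories of {model.kind} (b={model.b}, "
                f"noise={model.noise}) produced no spike within "
                f"{max_steps * dt:.3g} ms")
        va = v[alive]
        va = va + drift(va) * dt
        if sigma:
            va = va + sigma * rng.standard_normal(alive.size)
        v[alive] = va
        crossed = va >= thresh
        if crossed.any():
            # all particles started together, so the global step counter is
            # each particle's own elapsed step count; record and retire
            steps[alive[crossed]] = taken
            alive = alive[~crossed]
    isis = steps * dt
    if model.kind == "NIF" and model.tau > 0:
        isis = isis + model.tau
    return ISISequence(isis, meta={"model": model, "seed": seed,
                                   "sim_step": dt})


def sample_nif_exact(model: NeuronModel, n: int, seed=None) -> ISISequence:
    """Exact NIF ISI draws: tau + InverseGaussian(mean 1/b, shape 1/D).

    In the D -> 0 limit this degenerates to the constant tau + 1/b.
    """
    if model.kind != "NIF":
        raise ValueError("exact sampling is defined for the NIF model only")
    n = int(n)
    if model.noise == 0:
        return ISISequence(np.full(n, model.tau + 1.0 / model.b),
                           meta={"model": model, "seed": seed})
    dist = ShiftedInverseGaussian(model.tau, model.b, 1.0 / model.noise)
    seq = dist.sample(n, seed=seed)
    seq.meta["model"] = model
    return seq


_PARAM_GRIDS = {
    # printed parameter ranges for the universality sweeps
    "LIF": {"b": np.arange(1.5, 5.75 + 1e-9, 0.25),
            "a": np.concatenate([np.arange(0.1, 1.0 + 1e-9, 0.1),
                                 np.arange(1.25, 3.0 + 1e-9, 0.25)])},
    "QIF": {"b": np.arange(0.25, 4.75 + 1e-9, 0.25),
            "a": np.arange(0.25, 2.75 + 1e-9, 0.25)},
}


def parameter_grid(kind: str) -> dict:
    """The default (drift, noise) sweep grid for LIF or QIF."""
    g = _PARAM_GRIDS[kind]
    return {k: v.copy() for k, v in g.items()}


def calibrate_params(kind: str, target_rate: float, target_cv: float,
                     tau: float = 0.0, n_sim: int = 4000, seed: int = 12345,
                     tol: float = 0.02) -> NeuronModel:
    """Find model parameters whose firing rate and C_V match the targets.

    NIF and GISI are solved in closed form; LIF and QIF by Nelder-Mead on
    moments of a fixed-seed simulation (common random numbers keep the
    objective deterministic and smooth).  Raises if the target is outside the
    model's reachable (rate, C_V) region.
    """
    if target_rate <= 0 or target_cv <= 0:
        raise ValueError("targets must be positive")
    if kind == "GISI":
        shape = 1.0 / target_cv**2
        scale = 1.0 / (target_rate * shape)
        return NeuronModel("GISI", shape=shape, scale=scale)
    if kind == "NIF":
        mean = 1.0 / target_rate
        if mean <= tau:
            raise ValueError(
                f"target rate {target_rate} unreachable: mean ISI {mean} ms "
                f"is not above the refractory period {tau} ms")
        b = 1.0 / (mean - tau)
        sd = target_cv * mean
        lam = (1.0 / b) ** 3 / sd**2
        return NeuronModel("NIF", b=b, noise=1.0 / lam, tau=tau)
    if kind not in ("LIF", "QIF"):
        raise ValueError(f"unknown neuron kind {kind!r}")

    def measured(x):
        b, a = np.exp(x)
        m = NeuronModel(kind, b=b, noise=a)
        isis = simulate_isis(m, n_sim, seed=seed,
                             sim_step=max(_mean_isi_guess(m) * 2e-3, 1e-4))
        vals = isis.intervals
        return 1.0 / vals.mean(), vals.std() / vals.mean()

    def loss(x):
        try:
            rate, cv = measured(x)
        except (RuntimeError, ValueError):
            return 1e6
        return (math.log(rate / target_rate)) ** 2 + (
            math.log(cv / target_cv)) ** 2

    x0 = np.log([2.0, 0.5]) if kind == "LIF" else np.log([1.0, 1.0])
    res = optimize.minimize(loss, x0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-6,
                                     "maxfev": 120})
    b, a = np.exp(res.x)
    model = NeuronModel(kind, b=float(b), noise=float(a))
    rate, cv = measured(res.x)
    if abs(math.log(rate / target_rate)) > 5 * tol or \
            abs(math.log(cv / target_cv)) > 5 * tol:
        raise ValueError(
            f"{kind} target (rate={target_rate}, cv={target_cv}) not "
            f"reachable; best found rate={rate:.4g}, cv={cv:.4g}")
    return model
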