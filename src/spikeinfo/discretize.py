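"""Time binning: continuous spike trains -> binary sequences and count laws.

At resolution dt the renewal process is described by the interevent count
distribution F(n) (probability that the silence between successive event
bins is exactly n bins) and the count survival function w(n) (at least n
bins).  Two constructions are provided: the exact bin integrals
F(n) = Phi(n dt) - Phi((n+1) dt), w(n) = Phi(n dt), and the small-dt
approximations F(n) ~ phi(n dt) dt, w(n) ~ Phi(n dt), which coincide as
dt -> 0.  The mean count obeys <T> + 1 = 1/(mu dt) up to O(dt).

Bins are half-open [k dt, (k+1) dt), 0-based.  The symbol alphabet is
binary: bins holding more than one spike are clipped to "1" and the clip
count reported, since the analyses assume dt below the refractory/ISI scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .isi import ISIDistribution, ISISequence

#: truncation: the count chain is cut where w(n) drops below this mass.
#: The tail mass is tracked, not renormalized, so truncation is auditable.
TAIL_TOL = 1e-9


@dataclass
class DiscretizedRenewal:
    """Interevent count law of a renewal process at resolution dt (ms).

    ``F[n]`` for n < n_max and ``w[n]`` for n <= n_max, with
    w(n+1) = w(n) - F(n); ``tail_mass`` = w(n_max) is the probability beyond
    the truncation point, and ``tail_hazard`` the conditional per-bin event
    probability carried by the surrogate tail state.
    """

    dt: float
    F: np.ndarray
    w: np.ndarray
    n_max: int
    tail_mass: float
    tail_hazard: float
    mode: str = "exact"
    meta: dict = field(default_factory=dict)

    @property
    def mean_count(self) -> float:
        """<T> = sum n F(n), ignoring the truncated tail."""
        return float(np.sum(np.arange(self.n_max) * self.F))

    def hazards(self) -> np.ndarray:
        """Per-state event probabilities F(n)/w(n) for n < n_max."""
        return self.F / self.w[:-1]


def discretize_distribution(dist: ISIDistribution, dt: float,
                            mode: str = "exact",
                            tail_tol: float = TAIL_TOL) -> DiscretizedRenewal:
    """Build F(n) and w(n) from an ISI law at resolution dt.

    mode "exact" integrates the density over each bin; mode "small_dt" uses
    the infinitesimal-resolution approximations F(n) = phi(n dt) dt.
    A dt above the mean ISI triggers a warning: the renewal-in-counts
    picture degrades once bins can swallow whole intervals.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if mode not in ("exact", "small_dt"):
        raise ValueError("mode must be 'exact' or 'small_dt'")
    m = dist.moments()
    if dt > m.mean_isi:
        warnings.warn(
            f"dt={dt} exceeds the mean ISI {m.mean_isi:.4g}; the binary "
            f"renewal-in-counts approximation degrades", stacklevel=2)

    # find the truncation index from the survival function
    hi = dist.upper_limit()
    n_max = int(np.ceil(hi / dt)) + 1
    grid = dt * np.arange(n_max + 1)
    w = np.asarray(dist.survival(grid), dtype=float)
    keep = int(np.searchsorted(-w, -tail_tol))  # first n with w < tail_tol
    keep = max(keep, 2)
    n_max = min(keep, n_max)
    w = w[: n_max + 1]

    if mode == "exact":
        F = w[:-1] - w[1:]
    else:
        F = np.asarray(dist.density(grid[:n_max]), dtype=float) * dt
        F = np.minimum(F, w[:-1])  # keep w - F >= 0 where phi*dt overshoots
    # conditional hazard beyond the cut, for the surrogate tail state
    w_next = float(dist.survival((n_max + 1) * dt))
    tail_mass = float(w[-1])
    tail_hazard = (tail_mass - w_next) / tail_mass if tail_mass > 0 else 1.0
    return DiscretizedRenewal(dt=dt, F=F, w=w, n_max=n_max,
                              tail_mass=tail_mass, tail_hazard=tail_hazard,
                              mode=mode, meta={"family": dist.family})


def empirical_counts(disc_or_counts, n_max: int | None = None):
    """Empirical F(n) from a list of interevent counts."""
    counts = np.asarray(disc_or_counts, dtype=np.int64)
    top = int(counts.max()) if n_max is None else n_max
    F = np.bincount(counts, minlength=top + 1) / counts.size
    return F


def bin_spike_train(spike_times, dt: float, duration: float | None = None):
    """Binary spike/quiescence sequence from sorted event times.

    Returns (symbols, n_clipped): symbol 1 iff the bin holds >= 1 spike;
    n_clipped counts bins where more than one spike was collapsed.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    if t.size and t[0] < 0:
        raise ValueError("spike times must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is not None:
        n_bins = int(np.ceil(duration / dt))
    elif t.size:
        # through the bin containing the last spike
        n_bins = int(t[-1] // dt) + 1
    else:
        n_bins = 1
    symbols = np.zeros(n_bins, dtype=np.int8)
    if t.size:
        idx = np.minimum((t // dt).astype(np.int64), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        symbols[counts > 0] = 1
        n_clipped = int(np.sum(counts > 1))
    else:
        n_clipped = 0
    return symbols, n_clipped


def isis_to_counts(isis: ISISequence | np.ndarray, dt: float) -> np.ndarray:
    """Map each ISI to its silent-bin count (floor convention).

    An ISI of length u spans floor(u/dt) whole silent bins between the two
    event bins; these counts build the empirical F(n).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    vals = isis.intervals if isinstance(isis, ISISequence) else np.asarray(isis)
    return (vals // dt).astype(np.int64)


def write_symbols(symbols, path) -> None:
    """Write a binary sequence as unpadded 0/1 characters on one line."""
    from pathlib import Path

    Path(path).write_text("".join(str(int(s)) for s in symbols) + "\n")
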