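"""Minimal unifilar presentations (epsilon-machines) of binned spike trains.

For a renewal process observed at resolution dt, the causal state is the
number of bins since the last spike: from count-state n the machine emits a
spike with the hazard probability F(n)/w(n) and resets to state 0, or emits
silence and moves to state n+1.  Three topologies arise: a single state
(Poisson), a finite chain ending in a self-loop (eventually Poisson), and an
unbounded chain, which is truncated where the count survival drops below a
tolerance and closed with a self-loop state carrying the conditional tail
hazard.  An alternating renewal process (ARP) couples two such chains: a
spike emitted from chain m resets to state 0 of the other modality.

All information quantities are computed exactly from the machine:

* h_mu      entropy of the next symbol given the state (exact for unifilar
            machines),
* C_mu      Shannon entropy of the stationary state distribution,
* H(L)      block entropy via a forward pass over prefix classes (for a
            renewal chain the classes are "last spike j bins ago" plus one
            no-spike-yet mixture, so the pass is exact and O(L * states)),
* E(dt)     block mutual information I[X_{-L:0}; X_{0:L}] = 2 H(L) - H(2L),
            extrapolated geometrically in L,
* anatomy   r_mu from H[X_0 | S_0, future-window], b_mu = h_mu - r_mu, and
            q_mu, sigma_mu from the single-measurement identities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .discretize import DiscretizedRenewal
from .isi import safe_log2, xlog2x

#: relative hazard variation below which consecutive states are merged into
#: a geometric (self-loop) tail; requires at least this many stable states
GEOM_TOL = 1e-6
GEOM_RUN = 10

#: class-probability floor for the pruned mixed-state pass (ARP machines)
PRUNE_TOL = 1e-13
MAX_CLASSES = 200_000


def binary_entropy(p):
    """H_b(p) in bits, elementwise, with 0 log 0 = 0."""
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    q = 1.0 - p
    out = -(p * np.log2(np.maximum(p, 1e-300))
            + q * np.log2(np.maximum(q, 1e-300)))
    return float(out) if out.ndim == 0 else out


@dataclass
class EpsilonMachine:
    """A unifilar binary-alphabet hidden Markov model.

    emit1[s] is the spike probability from state s; next1[s]/next0[s] the
    successor on spike/silence (unifilarity: one successor per symbol).
    ``topology`` is one of poisson / eventually_poisson / renewal / arp.
    """

    dt: float
    emit1: np.ndarray
    next0: np.ndarray
    next1: np.ndarray
    stationary: np.ndarray
    topology: str
    labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.emit1.size

    def spike_probability(self) -> float:
        """Pr(X_0 = 1) under stationarity."""
        return float(self.stationary @ self.emit1)

    def transition_matrix(self) -> np.ndarray:
        """Dense row-stochastic state transition matrix (symbols summed)."""
        n = self.n_states
        T = np.zeros((n, n))
        for s in range(n):
            T[s, self.next1[s]] += self.emit1[s]
            T[s, self.next0[s]] += 1.0 - self.emit1[s]
        return T

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "dt": self.dt,
            "topology": self.topology,
            "states": [
                {
                    "index": int(s),
                    "label": self.labels[s] if self.labels else str(s),
                    "stationary": float(self.stationary[s]),
                    "edges": [
                        {"symbol": 1, "p": float(self.emit1[s]),
                         "to": int(self.next1[s])},
                        {"symbol": 0, "p": float(1 - self.emit1[s]),
                         "to": int(self.next0[s])},
                    ],
                }
                for s in range(self.n_states)
            ],
        }
        return json.dumps(doc, indent=1)

    def to_dot(self) -> str:
        lines = ["digraph epsilon_machine {", "  rankdir=LR;"]
        for s in range(self.n_states):
            lab = self.labels[s] if self.labels else str(s)
            lines.append(f'  {s} [label="{lab}"];')
            if self.emit1[s] > 0:
                lines.append(
                    f'  {s} -> {self.next1[s]} '
                    f'[label="{self.emit1[s]:.4g}|1"];')
            if self.emit1[s] < 1:
                lines.append(
                    f'  {s} -> {self.next0[s]} '
                    f'[label="{1 - self.emit1[s]:.4g}|0"];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _geometric_cut(hazards: np.ndarray, tol: float = GEOM_TOL,
                   run: int = GEOM_RUN) -> int:
    """Earliest index k such that hazards[k:] is constant within relative
    tolerance over at least ``run`` states (including the end); otherwise
    len(hazards) - 1 (cut only at the truncation tail state)."""
    n = hazards.size
    if n == 1:
        return 0
    ref = hazards[-1]
    scale = max(abs(ref), 1e-15)
    k = n - 1
    while k > 0 and abs(hazards[k - 1] - ref) <= tol * scale:
        k -= 1
    if n - k >= run or k == 0:
        return k
    return n - 1


def _chain_stationary(hazards: np.ndarray) -> np.ndarray:
    """Stationary law of a count chain 0..K with self-loop tail at K.

    Renewal theory gives pi(n) proportional to the machine's own count
    survival s(n) = prod_{i<n} (1 - h_i), with the tail state absorbing the
    geometric continuation: pi(K) proportional to s(K)/h_K.
    """
    K = hazards.size - 1
    s = np.concatenate([[1.0], np.cumprod(1.0 - hazards[:-1])])
    if hazards[K] <= 0:
        raise ValueError("tail state hazard must be positive (else the "
                         "machine never spikes from the tail)")
    u = s.copy()
    u[K] = s[K] / hazards[K]
    return u / u.sum()


def build_renewal_machine(disc: DiscretizedRenewal,
                          geom_tol: float = GEOM_TOL) -> EpsilonMachine:
    """Epsilon-machine of a discretized renewal process.

    Auto-detects the Poisson (single state) and eventually-Poisson (chain
    with geometric tail) topologies within ``geom_tol``; otherwise builds the
    generic truncated count chain closed by a conditional-hazard self-loop.
    """
    w = disc.w
    if np.any(w[:-1] <= 0):
        raise ValueError("count survival w(n) hit zero before truncation; "
                         "inconsistent F/w")
    hazards = np.append(disc.F / w[:-1], disc.tail_hazard)
    if np.any(hazards < -1e-12) or np.any(hazards > 1 + 1e-12):
        raise ValueError("invalid hazards derived from F/w")
    hazards = np.clip(hazards, 0.0, 1.0)

    cut = _geometric_cut(hazards, tol=geom_tol)
    h = hazards[: cut + 1].copy()
    K = h.size - 1
    if K == 0:
        topology = "poisson"
    elif cut < hazards.size - 1:
        topology = "eventually_poisson"
    else:
        topology = "renewal"
    next1 = np.zeros(K + 1, dtype=np.int64)
    next0 = np.minimum(np.arange(K + 1) + 1, K)
    pi = _chain_stationary(h)
    labels = [str(n) for n in range(K)] + [f"{K}+"]
    return EpsilonMachine(dt=disc.dt, emit1=h, next0=next0, next1=next1,
                          stationary=pi, topology=topology, labels=labels,
                          meta={"n_max": disc.n_max,
                                "tail_mass": disc.tail_mass})


def build_arp_machine(disc1: DiscretizedRenewal, disc2: DiscretizedRenewal,
                      tol: float = 1e-9,
                      geom_tol: float = GEOM_TOL) -> EpsilonMachine:
    """Epsilon-machine of an alternating renewal process.

    Two count chains tagged by modality; a spike emitted from chain m resets
    to state 0 of the other chain.  Each chain is independently collapsed to
    its minimal renewal topology.  Raises if the two interevent count
    distributions agree within ``tol`` (the chains would merge into a single
    renewal machine; use build_renewal_machine).
    """
    if abs(disc1.dt - disc2.dt) > 1e-12:
        raise ValueError("both modalities must share the same dt")
    n = min(disc1.F.size, disc2.F.size)
    if np.max(np.abs(disc1.F[:n] - disc2.F[:n])) < tol and \
            disc1.F.size == disc2.F.size:
        raise ValueError(
            "modality count distributions are equal within tolerance; "
            "this is a plain renewal process (use build_renewal_machine)")

    chains = []
    for disc in (disc1, disc2):
        w = disc.w
        if np.any(w[:-1] <= 0):
            raise ValueError("count survival hit zero before truncation")
        hz = np.clip(np.append(disc.F / w[:-1], disc.tail_hazard), 0.0, 1.0)
        cut = _geometric_cut(hz, tol=geom_tol)
        chains.append(hz[: cut + 1])
    h1, h2 = chains
    K1, K2 = h1.size, h2.size
    emit1 = np.concatenate([h1, h2])
    idx1 = np.arange(K1)
    idx2 = K1 + np.arange(K2)
    next0 = np.concatenate([np.minimum(idx1 + 1, K1 - 1),
                            np.minimum(idx2 + 1, K1 + K2 - 1)])
    next1 = np.concatenate([np.full(K1, K1, dtype=np.int64),
                            np.zeros(K2, dtype=np.int64)])

    # stationary: each chain visited once per cycle; within a chain the
    # occupation is proportional to that chain's own count survival
    def chain_mass(h):
        s = np.concatenate([[1.0], np.cumprod(1.0 - h[:-1])])
        u = s.copy()
        u[-1] = s[-1] / h[-1] if h[-1] > 0 else s[-1]
        return u

    u1, u2 = chain_mass(h1), chain_mass(h2)
    pi = np.concatenate([u1, u2])
    pi /= pi.sum()
    labels = [f"{n}_1" for n in range(K1)] + [f"{n}_2" for n in range(K2)]
    return EpsilonMachine(dt=disc1.dt, emit1=emit1, next0=next0, next1=next1,
                          stationary=pi, topology="arp", labels=labels,
                          meta={"chain_sizes": (K1, K2)})


# ---------------------------------------------------------------------------
# exact information quantities
# ---------------------------------------------------------------------------

def statistical_complexity(m: EpsilonMachine) -> float:
    """C_mu = H[S+] in bits: entropy of the stationary state distribution."""
    return float(-np.sum(xlog2x(m.stationary)))


def entropy_rate(m: EpsilonMachine) -> float:
    """h_mu in bits/symbol, exact for a unifilar machine:
    the stationary average of the per-state symbol entropy."""
    return float(m.stationary @ binary_entropy(m.emit1))


def _is_renewal_chain(m: EpsilonMachine) -> bool:
    return m.topology in ("poisson", "eventually_poisson", "renewal")


def _renewal_block_profile(m: EpsilonMachine, L: int) -> np.ndarray:
    """H(l) for l = 0..L for a renewal count chain, exactly.

    Prefix classes after l symbols are "last spike at position j" (state
    known) and "no spike yet" (the stationary mixture conditioned on l
    silences); their probabilities involve only the count survival from
    state 0 and the propagated stationary vector.
    """
    h = m.emit1
    K = h.size - 1
    pi = m.stationary
    p1 = m.spike_probability()
    hb = binary_entropy(h)
    # survival from state 0 for l = 0..L-1 and per-state entropy of the
    # deterministic classes, cumulated: A[l] = sum_{d<l} s0[d] hb(state d)
    idx = np.minimum(np.arange(L), K)
    one_minus = 1.0 - h[idx]
    s0 = np.concatenate([[1.0], np.cumprod(one_minus[:-1])])
    A = np.concatenate([[0.0], np.cumsum(s0 * hb[idx])])
    # no-spike-yet class: propagate the stationary vector through silences
    v = pi.copy()
    cond = np.empty(L)
    for l in range(L):
        mass = v.sum()
        if mass <= 0:
            cond[l] = p1 * A[l]
            continue
        mix_haz = float(v @ h) / mass
        cond[l] = mass * binary_entropy(mix_haz) + p1 * A[l]
        v = v * (1.0 - h)
        v_new = np.zeros_like(v)
        v_new[1:] = v[:-1]
        v_new[K] += v[K]
        v = v_new
    return np.concatenate([[0.0], np.cumsum(cond)])


def _generic_block_profile(m: EpsilonMachine, L: int,
                           init: np.ndarray | None = None,
                           prune_tol: float = PRUNE_TOL,
                           max_classes: int = MAX_CLASSES):
    """H(l) for l = 0..L by a pruned forward pass over mixed states.

    Classes are posteriors over states given the emitted prefix, merged by a
    rounded sparse key.  Pruned probability mass is tracked and reported in
    the second return value (an upper bound on the entropy deficit is
    dropped_mass * L bits).
    """
    emit1, next0, next1 = m.emit1, m.next0, m.next1
    start = m.stationary if init is None else init
    post0 = {s: p for s, p in enumerate(np.asarray(start, float)) if p > 0}
    classes = {_post_key(post0): (1.0, post0)}
    cond = np.zeros(L)
    dropped = 0.0
    for l in range(L):
        new: dict = {}
        for prob, post in classes.values():
            p1 = sum(q * emit1[s] for s, q in post.items())
            cond[l] += prob * binary_entropy(p1)
            if p1 > 0:
                nxt: dict = {}
                for s, q in post.items():
                    if emit1[s] > 0:
                        t = next1[s]
                        nxt[t] = nxt.get(t, 0.0) + q * emit1[s] / p1
                _accumulate(new, nxt, prob * p1)
            if p1 < 1:
                nxt = {}
                for s, q in post.items():
                    if emit1[s] < 1:
                        t = next0[s]
                        nxt[t] = nxt.get(t, 0.0) + q * (1 - emit1[s]) / (1 - p1)
                _accumulate(new, nxt, prob * (1 - p1))
        items = sorted(new.values(), key=lambda x: -x[0])
        if len(items) > max_classes:
            dropped += sum(p for p, _ in items[max_classes:])
            items = items[:max_classes]
        kept = [(p, d) for p, d in items if p >= prune_tol]
        dropped += sum(p for p, _ in items) - sum(p for p, _ in kept)
        total = sum(p for p, _ in kept)
        classes = {_post_key(d): (p / total, d) for p, d in kept}
    return np.concatenate([[0.0], np.cumsum(cond)]), dropped


def _post_key(post: dict) -> tuple:
    return tuple(sorted((s, round(q, 10)) for s, q in post.items()))


def _accumulate(store: dict, post: dict, prob: float) -> None:
    key = _post_key(post)
    if key in store:
        store[key] = (store[key][0] + prob, store[key][1])
    else:
        store[key] = (prob, post)


def _arp_block_profile(m: EpsilonMachine, L: int, q_decimals: int = 6,
                       max_classes: int = 100_000):
    """H(l) for l = 0..L for a two-chain ARP machine, vectorized.

    Once the prefix contains a spike, the posterior is supported on one
    state per chain with a common silence count n, so a class is a pair
    (n, q) with q = Pr(modality 1 | prefix); classes are merged on a
    rounded-q grid.  The pre-first-spike stationary mixture is propagated
    as a separate dense vector.  Returns (profile, dropped_mass).
    """
    K1, K2 = m.meta["chain_sizes"]
    h1, h2 = m.emit1[:K1], m.emit1[K1:]
    ncap = max(K1, K2) - 1
    # virgin (no spike yet) class: dense unnormalized posterior per chain
    v1 = m.stationary[:K1].copy()
    v2 = m.stationary[K1:].copy()
    # spiked classes: parallel arrays
    ns = np.empty(0, dtype=np.int64)
    qs = np.empty(0)
    ps = np.empty(0)
    cond = np.zeros(L)
    dropped = 0.0
    scale = 10.0 ** q_decimals
    for l in range(L):
        e1 = h1[np.minimum(ns, K1 - 1)]
        e2 = h2[np.minimum(ns, K2 - 1)]
        pspike = qs * e1 + (1.0 - qs) * e2
        cond[l] = float(ps @ binary_entropy(pspike)) if ps.size else 0.0
        # virgin class contribution
        sp1 = float(v1 @ h1)
        sp2 = float(v2 @ h2)
        mass = v1.sum() + v2.sum()
        if mass > 1e-300:
            cond[l] += mass * binary_entropy((sp1 + sp2) / mass)
        # branch the spiked classes
        new_n = np.concatenate([np.minimum(ns + 1, ncap), np.zeros_like(ns)])
        with np.errstate(divide="ignore", invalid="ignore"):
            q_silence = np.where(pspike < 1.0,
                                 qs * (1 - e1) / np.maximum(1 - pspike, 1e-300),
                                 0.0)
            q_spike = np.where(pspike > 0,
                               (1.0 - qs) * e2 / np.maximum(pspike, 1e-300),
                               0.0)
        new_q = np.concatenate([q_silence, q_spike])
        new_p = np.concatenate([ps * (1 - pspike), ps * pspike])
        # virgin spike branch joins the spiked classes at n = 0
        if sp1 + sp2 > 1e-300:
            new_n = np.append(new_n, 0)
            new_q = np.append(new_q, sp2 / (sp1 + sp2))
            new_p = np.append(new_p, sp1 + sp2)
        # virgin silence branch: advance both chains (tail states self-loop)
        v1 = v1 * (1 - h1)
        tail1 = v1[-1]
        v1[1:] = v1[:-1]
        v1[0] = 0.0
        v1[-1] += tail1
        v2 = v2 * (1 - h2)
        tail2 = v2[-1]
        v2[1:] = v2[:-1]
        v2[0] = 0.0
        v2[-1] += tail2
        # merge classes on the (n, rounded q) grid
        live = new_p > 1e-300
        new_n, new_q, new_p = new_n[live], new_q[live], new_p[live]
        key = new_n.astype(np.float64) * (scale * 10) + np.round(new_q * scale)
        uniq, inv = np.unique(key, return_inverse=True)
        ps = np.bincount(inv, weights=new_p)
        qs = np.bincount(inv, weights=new_p * new_q) / ps
        ns = np.bincount(inv, weights=new_p * new_n) / np.maximum(ps, 1e-300)
        ns = np.round(ns).astype(np.int64)
        if ps.size > max_classes:
            order = np.argsort(ps)[::-1]
            keep = order[:max_classes]
            dropped += float(ps.sum() - ps[keep].sum())
            ns, qs, ps = ns[keep], qs[keep], ps[keep]
    return np.concatenate([[0.0], np.cumsum(cond)]), dropped


def block_entropy_profile(m: EpsilonMachine, L: int) -> np.ndarray:
    """H(l) in bits for l = 0..L (H(0) = 0), exact on the machine."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if _is_renewal_chain(m):
        return _renewal_block_profile(m, L)
    if m.topology == "arp":
        prof, dropped = _arp_block_profile(m, L)
    else:
        prof, dropped = _generic_block_profile(m, L)
    if dropped * L > 1e-3:
        import warnings

        warnings.warn(f"block-entropy pass pruned {dropped:.2e} probability "
                      f"mass; entropies may be low by up to {dropped * L:.2e}"
                      f" bits", stacklevel=2)
    return prof


def block_entropy(m: EpsilonMachine, L: int) -> float:
    """H(dt, T = L dt): entropy of an L-symbol block, in bits."""
    return float(block_entropy_profile(m, L)[L])


def entropy_rate_estimators(m: EpsilonMachine, L: int):
    """The two finite-time entropy-rate estimators, in bits per ms:
    H(dt,T)/T and (H(dt,T) - H(dt,T-dt))/dt with T = L dt.  The difference
    estimator sheds the E(T)/T transient and converges faster."""
    if L < 2:
        raise ValueError("L must be >= 2")
    prof = block_entropy_profile(m, L)
    ratio = prof[L] / (L * m.dt)
    diff = (prof[L] - prof[L - 1]) / m.dt
    return ratio, diff


@dataclass
class ExcessEntropyResult:
    """E(dt) estimate: raw block mutual information at the largest window,
    plus a geometric-tail extrapolation of the window sequence."""

    raw: float
    extrapolated: float
    L: int
    converged: bool
    profile: np.ndarray  # E_l for l = 1..L
    tail_bound: float

    def __float__(self):
        return self.extrapolated


def _geometric_extrapolate(values: np.ndarray):
    """Extrapolate a converging sequence by fitting a geometric tail to its
    increments; returns (limit, converged, tail_bound)."""
    v = np.asarray(values, float)
    if v.size < 4:
        return float(v[-1]), False, math.inf
    d = np.diff(v)
    tail = d[-3:]
    if np.max(np.abs(tail)) < 1e-14:
        return float(v[-1]), True, 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = tail[1:] / tail[:-1]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        return float(v[-1]), False, math.inf
    r = float(np.median(ratios))
    if not 0 <= r < 0.999:
        return float(v[-1]), abs(d[-1]) < 1e-9, abs(d[-1])
    corr = d[-1] * r / (1 - r)
    return float(v[-1] + corr), True, abs(corr)


def excess_entropy_discrete(m: EpsilonMachine, L_max: int) -> ExcessEntropyResult:
    """E(dt) as the past/future block mutual information on the machine.

    By stationarity I[X_{-L:0}; X_{0:L}] = 2 H(L) - H(2L); the window
    sequence increases to E(dt) and is closed by a geometric-tail fit.
    """
    if L_max < 2:
        raise ValueError("L_max must be >= 2")
    prof = block_entropy_profile(m, 2 * L_max)
    ls = np.arange(1, L_max + 1)
    E_l = 2 * prof[ls] - prof[2 * ls]
    limit, converged, bound = _geometric_extrapolate(E_l)
    return ExcessEntropyResult(raw=float(E_l[-1]), extrapolated=limit,
                               L=L_max, converged=converged, profile=E_l,
                               tail_bound=bound)


# ---------------------------------------------------------------------------
# information anatomy
# ---------------------------------------------------------------------------

@dataclass
class InfoAnatomy:
    """The information anatomy of one binned observation at resolution dt.

    h_mu, b_mu, r_mu, q_mu in bits/symbol; C_mu, E, sigma_mu in bits.
    The identities h_mu = r_mu + b_mu, E = b_mu + sigma_mu + q_mu and
    H[X_0] = q_mu + 2 b_mu + r_mu close the decomposition.
    """

    dt: float
    h_mu: float
    C_mu: float
    E: float
    b_mu: float
    r_mu: float
    q_mu: float
    sigma_mu: float
    H0: float
    L: int
    converged: bool = True
    meta: dict = field(default_factory=dict)


def _renewal_future_conditional(m: EpsilonMachine, K: int) -> np.ndarray:
    """r(k) = H[X_0 | S_0, X_{1:k+1}] for k = 1..K on a renewal chain.

    Uses H[X_0 | s, F] = H(X_0, F | s) - H(F | s): word entropies from a
    deterministic state come from the g-vector recursion, and the
    length-k word entropy from the post-X_0 two-atom mixture has a closed
    forward form because both atoms evolve deterministically until the
    first spike merges them into state 0.
    """
    h = m.emit1
    K_state = h.size - 1
    pi = m.stationary
    N = h.size
    hb = binary_entropy(h)
    # g_l[n] = E[H_b(hazard at step l) | start n]; W[n, k] = word entropy
    g = hb.copy()
    cumG = np.zeros((K + 2, N))
    W0 = np.zeros(K + 2)  # word entropy from state 0, by length
    for l in range(1, K + 2):
        cumG[l] = cumG[l - 1] + g
        W0[l] = cumG[l][0]
        g = h * g[0] + (1.0 - h) * np.append(g[1:], g[-1])
    # extended log-survival for arbitrary start states
    ext = K_state + K + 2
    hx = h[np.minimum(np.arange(ext), K_state)]
    LS = np.concatenate([[0.0], np.cumsum(np.log(np.maximum(1 - hx, 1e-300)))])

    ls = np.arange(K)  # future steps 0..K-1
    nxt0 = np.minimum(np.arange(N) + 1, K_state)
    # atom A: state 0 after a spike; atom B: state n+1 after silence
    survA = np.exp(LS[ls])                             # (K,)
    hazA = hx[ls]
    r = np.zeros(K)
    for s in range(N):
        if pi[s] <= 0:
            continue
        sb = nxt0[s]
        A = h[s] * survA
        B = (1.0 - h[s]) * np.exp(LS[sb + ls] - LS[sb])
        P0 = A + B
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = np.where(P0 > 0,
                           (A * hazA + B * hx[sb + ls]) / np.maximum(P0, 1e-300),
                           0.0)
        fire = P0 * eta
        # Hword(ms_s, k) = sum_{l<k} P0 H_b(eta) + sum_{l<k} fire[l] W0[k-1-l]
        base = np.cumsum(P0 * binary_entropy(eta))
        cont = np.convolve(fire, W0[:K])[:K]
        # r_s(k) = Hword(delta_s, k+1) - Hword(ms_s, k), k = 1..K
        r += pi[s] * (cumG[2: K + 2, s] - base - cont)
    return r


def _generic_future_conditional(m: EpsilonMachine, K: int) -> np.ndarray:
    """r(k) for small machines by the pruned mixed-state pass."""
    N = m.n_states
    pi = m.stationary
    r = np.zeros(K)
    for s in range(N):
        if pi[s] <= 0:
            continue
        init = np.zeros(N)
        init[s] = 1.0
        joint, _ = _generic_block_profile(m, K + 1, init=init)
        mix = np.zeros(N)
        mix[m.next1[s]] += m.emit1[s]
        mix[m.next0[s]] += 1.0 - m.emit1[s]
        fut, _ = _generic_block_profile(m, K, init=mix)
        for k in range(1, K + 1):
            r[k - 1] += pi[s] * (joint[k + 1] - fut[k])
    return r


def anatomy_discrete(m: EpsilonMachine, L_max: int) -> InfoAnatomy:
    """Full information anatomy of the machine at its resolution dt.

    h_mu and H[X_0] are exact; E comes from the block mutual information and
    r_mu from the future-conditioned entropy of the present, both
    extrapolated in the window length; b_mu = h_mu - r_mu, and q_mu,
    sigma_mu follow from the information-diagram identities.
    """
    h_mu = entropy_rate(m)
    C_mu = statistical_complexity(m)
    H0 = binary_entropy(m.spike_probability())
    Eres = excess_entropy_discrete(m, L_max)
    if _is_renewal_chain(m):
        r_prof = _renewal_future_conditional(m, L_max)
    else:
        r_prof = _generic_future_conditional(m, min(L_max, 14))
    r_mu, r_conv, _ = _geometric_extrapolate(r_prof)
    r_mu = min(max(r_mu, 0.0), h_mu)
    b_mu = h_mu - r_mu
    q_mu = H0 - 2 * b_mu - r_mu
    sigma_mu = Eres.extrapolated - b_mu - q_mu
    return InfoAnatomy(dt=m.dt, h_mu=h_mu, C_mu=C_mu, E=Eres.extrapolated,
                       b_mu=b_mu, r_mu=r_mu, q_mu=q_mu, sigma_mu=sigma_mu,
                       H0=H0, L=L_max, converged=Eres.converged and r_conv,
                       meta={"E_raw": Eres.raw, "r_profile_tail": r_prof[-1]})
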