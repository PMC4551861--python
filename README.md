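# spikeinfo

Information anatomy of neural spike trains as a function of time resolution.

A spike train recorded from (or simulated by) a neuron is usually converted
into a binary sequence by counting spikes in time bins of size Δt, and any
information-theoretic statement about it — how random it is, how predictable,
how much memory it carries — then depends on Δt. `spikeinfo` computes these
quantities *exactly* for renewal spike trains (independent, identically
distributed interspike intervals) and alternating renewal processes (two ISI
laws drawn in strict alternation), and tracks how each quantity scales as
Δt → 0:

- **entropy rate** h<sub>μ</sub> = H[X₀ | X₋∞…X₋₁] — information generated per symbol;
  the Δt-entropy rate h<sub>μ</sub>/Δt diverges as μ·log₂(1/Δt), μ the firing rate;
- **statistical complexity** C<sub>μ</sub> = H[S⁺] — entropy of the causal states of
  the minimal unifilar hidden Markov model (ε-machine); diverges as log₂(1/Δt)
  with the differential entropy of the time-since-last-spike density as its
  nondivergent part;
- **excess entropy** E = I[past; future] — total predictable information;
  converges to ∫μtφ log₂(μφ) dt − 2∫μΦ log₂(μΦ) dt, with φ the ISI density
  and Φ its survival function;
- **bound information** b<sub>μ</sub> = I[X₀; future | past] — generated information
  that is actively stored; b<sub>μ</sub>/Δt converges to
  −μ(∬φφ′ log₂φ(t+t′) + log₂e − ∫φ log₂φ);
- the remaining atoms of the single-measurement entropy: ephemeral r<sub>μ</sub>,
  enigmatic q<sub>μ</sub>, and elusive σ<sub>μ</sub> information, closed by the identities
  h<sub>μ</sub> = r<sub>μ</sub> + b<sub>μ</sub>, E = b<sub>μ</sub> + σ<sub>μ</sub> + q<sub>μ</sub>, H[X₀] = q<sub>μ</sub> + 2b<sub>μ</sub> + r<sub>μ</sub>.

For a renewal process at resolution Δt the causal state is the number of
silent bins since the last spike, so the ε-machine is a count chain with
hazard probabilities F(n)/w(n); the package builds it, detects the Poisson
and eventually-Poisson collapses, and evaluates block entropies, block mutual
information and the conditional-entropy atoms exactly on the machine by
forward passes over prefix classes (no sampling, no word enumeration).

The package also ships the four spike-train generators used for the
cross-model comparison — the non-leaky (NIF, exact shifted inverse-Gaussian
ISIs), leaky (LIF) and quadratic (QIF) noise-driven integrate-and-fire
neurons, and gamma-distributed ISIs (GISI) — plus a sweep pipeline that maps
the rescaled, rate-free quantities against the ISI coefficient of variation
C<sub>V</sub> across models.

Intended users: computational neuroscientists and complex-systems researchers
who need exact baselines for entropy-rate/complexity estimators on point
processes, or who want the time-resolution scaling of an information measure
rather than a single number at an arbitrary bin size.

## Worked example

The drift-diffusion (non-leaky integrate-and-fire) neuron with hard
refractory period τ = 2 ms, unit drift and unit shape parameter has ISI law
τ + InverseGaussian(mean 1 ms, shape 1 ms):

```python
import spikeinfo as si

dist = si.ShiftedInverseGaussian(tau=2.0, b=1.0, lam=1.0)
m = dist.moments()
print(f"mean ISI  : {m.mean_isi:.3f} ms   rate: {m.firing_rate:.4f} /ms   CV: {m.cv:.4f}")
print(f"E limit   : {si.excess_entropy_limit(dist):.4f} bits")
print(f"b_mu rate : {si.bmu_rate_limit(dist):.4f} bits/ms")
hs, cs = si.hmu_scaling(dist), si.cmu_scaling(dist)
print(f"h_mu/dt ~ {hs.divergence_coefficient:.4f} * log2(1/dt) + {hs.nondivergent_part:.4f}  bits/ms")
print(f"C_mu    ~ {cs.divergence_coefficient:.4f} * log2(1/dt) + {cs.nondivergent_part:.4f}  bits")
for dt in (0.2, 0.05):
    mach = si.build_renewal_machine(si.discretize_distribution(dist, dt))
    an = si.anatomy_discrete(mach, int(30/dt))
    print(f"dt={dt:4} ms: states={mach.n_states:4d}  C_mu={an.C_mu:.3f}  h_mu={an.h_mu:.4f}  "
          f"E={an.E:.4f}  b_mu/dt={an.b_mu/dt:.4f}  sigma={an.sigma_mu:.4f}")
```

prints

```
mean ISI  : 3.000 ms   rate: 0.3333 /ms   CV: 0.3333
E limit   : 0.7500 bits
b_mu rate : 1.0504 bits/ms
h_mu/dt ~ 0.3333 * log2(1/dt) + 0.4217  bits/ms
C_mu    ~ 1.0000 * log2(1/dt) + 2.0607  bits
dt= 0.2 ms: states= 173  C_mu=4.415  h_mu=0.2351  E=0.7426  b_mu/dt=0.7147  sigma=0.6326
dt=0.05 ms: states= 689  C_mu=6.391  h_mu=0.0924  E=0.7557  b_mu/dt=0.9355  sigma=0.7267
```

Reading this: the process is highly *cryptic* — C<sub>μ</sub> grows without bound as
the bin size shrinks (6.4 bits of state memory already at 50 µs) while the
predictable information E saturates at 0.75 bits. The per-symbol entropy
rate h<sub>μ</sub> vanishes with Δt but the per-millisecond rate diverges
logarithmically at exactly the firing rate (1/3 per ms). The bound
information rate b<sub>μ</sub>/Δt is still 11% below its 1.05 bits/ms limit at
Δt = 50 µs — converging information estimates for spike trains genuinely
require sub-millisecond resolution.

The same quantities are available from the shell:

```bash
spikeinfo simulate --model nif --b 1 --noise 1 --tau 2 --n 100000 --seed 1 --out isis.txt
spikeinfo measures --dist dist.yaml --dt 0.1
spikeinfo arp --phi1 phi1.yaml --phi2 phi2.yaml
spikeinfo sweep --config sweep.yaml --out results.tsv
```

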