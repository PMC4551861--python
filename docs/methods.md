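# Methods

## Model class and assumptions

Everything in `spikeinfo` rests on two modelling assumptions:

1. **Renewal structure.** The spike train's interspike intervals (ISIs) are
   independent draws from a single law φ(t) (renewal process), or from two
   laws drawn in strict alternation (alternating renewal process, ARP). All
   processes are stationary and ergodic, with finite, strictly positive mean
   ISI — the continuum formulas all normalize by the firing rate
   μ = 1/E[ISI] and are meaningless when μ = 0.
2. **Binary observation.** At resolution Δt the process is observed as a
   spike/quiescence symbol per bin (half-open bins [kΔt, (k+1)Δt), 0-based).
   Bins containing more than one spike are clipped to "1" and counted; the
   analyses assume Δt sits below the refractory/ISI scale where clipping is
   rare, and the clip count makes violations auditable.

When Δt approaches the mean ISI, the binned process is no longer exactly
renewal in its counts (the position of a spike inside its bin carries
information). The discretizer warns in that regime; the machine-based
quantities are then bounds rather than exact values (h<sub>μ</sub> an upper bound, E
and C<sub>μ</sub> lower bounds, by data processing).

The canonical time unit is milliseconds throughout; conversions happen only
at I/O boundaries. All the "rescaled" comparison quantities
(C*, h*, E, b*) are dimensionless and verified unit-invariant in the tests.

## Exact machine computations

The ε-machine of a discretized renewal process is the count chain: state n
("n silent bins since the last spike") emits a spike with the hazard
probability F(n)/w(n) and resets, or advances to n+1. Three structural
specializations are detected automatically: a constant hazard collapses the
chain to a single state (memoryless process); a hazard that becomes constant
beyond some index yields a finite chain with a self-loop tail
(eventually-memoryless, e.g. a refractory Poisson neuron); otherwise the
chain is truncated where the count survival w(n) drops below 10⁻⁹ and closed
with a self-loop state carrying the conditional tail hazard. Truncated mass
is tracked, never renormalized. The stationary law is the renewal-theory
closed form π(n) ∝ w(n) (tail state: w/h), cross-checked against the
eigenproblem in the tests. Geometric-tail detection uses relative hazard
variation < 10⁻⁶ sustained over at least 10 states.

Quantities computed exactly on the machine:

- h<sub>μ</sub>: stationary average of the per-state symbol entropy (exact for
  unifilar models);
- C<sub>μ</sub>: entropy of π;
- H(L): block entropy by a forward pass over *prefix classes*. For a renewal
  chain, conditioning on the emitted prefix leaves only "last spike j bins
  ago" (state known) and "no spike yet" (the stationary mixture conditioned
  on silence) — L+1 classes, so the pass is exact with O(L·states) work. For
  ARP machines the post-first-spike posterior is a pair (silence count n,
  modality probability q); classes are merged on a rounded-q grid (10⁻⁶) and
  mass-pruned with the discarded probability tracked and a warning emitted
  when the implied entropy deficit could exceed 10⁻³ bits.
- E(Δt): the block mutual information I[X₋L:0; X0:L] = 2H(L) − H(2L)
  (stationarity), increasing in L and closed by a geometric-tail fit on its
  increments. Both the raw window value and the extrapolation are reported.
- r<sub>μ</sub>: H[X₀ | S₀, X₁:K₊₁] = Hword(δ_s, K+1) − Hword(ms_s, K) averaged over
  π, where the word entropies from a deterministic state come from a
  g-vector recursion and the post-present two-atom mixture evolves in closed
  form (both atoms move deterministically until the first spike merges
  them). Decreasing in K; geometric-tail extrapolated.
- b<sub>μ</sub> = h<sub>μ</sub> − r<sub>μ</sub>; q<sub>μ</sub> and σ<sub>μ</sub> from the information-diagram identities
  H[X₀] = q + 2b + r and E = b + σ + q. The identities therefore hold by
  construction; the independent content of the anatomy (h, H[X₀], E, r) is
  validated against brute-force word-enumeration oracles at small window
  lengths in the test suite, to ~10⁻¹⁰ bits.

## Continuum limits and scaling decompositions

The Δt → 0 limits are evaluated by adaptive quadrature (absolute tolerance
10⁻¹⁰, infinite limits truncated where the survival falls below 10⁻¹²,
breakpoints planted around the density peak for near-deterministic laws, and
0·log 0 ≡ 0 throughout):

- E → ∫μtφ log₂(μφ) − 2∫μΦ log₂(μΦ);
- finite-horizon E(T) via its five-term closed form, with E(0) = 0 and
  E(T) → E verified;
- C<sub>μ</sub>(Δt) ~ (μ∫₀ᵀΦ)·log₂(1/Δt) + const: coefficient 1 for a generic law
  (μ∫Φ = 1), 0 for memoryless, T/(T + 1/λ) for a refractory-Poisson with
  dead time T; the constant is the differential entropy of the
  time-since-last-spike density μΦ;
- h<sub>μ</sub>(Δt)/Δt ~ μ·log₂(1/Δt) − μ∫φ log₂φ;
- b<sub>μ</sub>(Δt)/Δt → −μ(∬φφ′ log₂φ(t+t′) + log₂e − ∫φ log₂φ). The constant is
  log₂e: that choice is forced by the requirement that the memoryless
  process store nothing (for exponential φ the three terms cancel exactly,
  verified symbolically and numerically).

Closed forms replace quadrature where they exist: exponential and gamma
differential entropies; exponential, refractory-Poisson and gamma cross
terms (the ISI-sum law is Gamma(2k) for gamma ISIs); the inverse-Gaussian
cross term reduces to one dimension because the family is closed under
convolution at fixed shape-to-mean² ratio. Every fast path is tested against
the generic nested quadrature and against Monte-Carlo pairing oracles.

Divergence coefficients are validated empirically by regressing the exact
machine values against log₂(1/Δt) over dyadic Δt grids.

**Rescaled (unit-free) quantities.** C* = lim C<sub>μ</sub>(Δt) + log₂(μΔt) =
−μ∫Φ log₂Φ; h* = lim h<sub>μ</sub>/(μΔt) + log₂(μΔt) = log₂μ − ∫φ log₂φ; E;
b* = lim b<sub>μ</sub>/(μΔt). Convention: the exactly-memoryless law reports
C* = 0 (its machine has a single state and C<sub>μ</sub>(Δt) ≡ 0, so the generic
rescaling does not apply); the generic formula is continuous through
C<sub>V</sub> = 1 and evaluates to log₂e there, so the two readings differ exactly at
the memoryless point — the convention follows the machine.

**Extrapolation to Δt → 0.** E(Δt) approaches its limit as O(Δt) with a
slowly varying correction; the discrete→continuum validations use quadratic
polynomial (Richardson) extrapolation in Δt over dyadic grids, which lands
within 0.4% of the quadrature value from {0.2, 0.1, 0.05}×ms grids (and
within 0.01% from finer grids) for the reference drift-diffusion law. At
Δt above ~10% of the mean ISI the approach is not monotone when the bin
size is commensurate with the refractory period; extrapolations should use
the small-Δt tail.

## Alternating renewal processes

Modality rates are reciprocal mean ISIs; the composite rate is
μ = 2μ⁽¹⁾μ⁽²⁾/(μ⁽¹⁾+μ⁽²⁾) (spikes per unit time over a full cycle), and the
stationary time fraction of modality m is μ^(other)/(μ⁽¹⁾+μ⁽²⁾). The
composite limits are

- E → H_b(μ₁/(μ₁+μ₂)) + time-fraction-weighted modality excess entropies
  (the H_b term is the stored modality bit; exactly 1 at equal rates);
- h<sub>μ</sub>/Δt ~ μ·log₂(1/Δt) + weighted modality differential-entropy rates;
- C<sub>μ</sub> ~ **1**·log₂(1/Δt) + weighted modality complexities + H_b.

Two coefficient choices here were genuinely open and were settled by the
exact machine rather than by formula manipulation: the h<sub>μ</sub> divergence
coefficient (candidates μ and μ/2) and the C<sub>μ</sub> coefficient (candidates 1
and 2, the latter suggested by counting chains). The stationary analysis —
chain weights are time fractions, each chain contributes its own renewal
divergence; state masses scale as Δt over O(1/Δt) states regardless of the
number of chains — gives μ and 1, and regression of the exact machine
quantities over dyadic Δt grids confirms both to a few percent. The scaling
objects retain both candidates, the regression value, and a discrepancy
flag.

The "noncomposite" comparison process is the renewal process whose ISI law
is the equal-weight mixture (φ₁+φ₂)/2 — the marginal law of a randomly
chosen interval, since the modalities alternate one draw each. Its h<sub>μ</sub>
divergence coefficient equals the ARP's composite rate exactly (both count
spikes per unit time), so the interesting comparisons are the nondivergent
parts and E; the comparison record reports all of them with the observed
orderings rather than asserting them.

Finite ARP samples start in modality 1 by default (a "stationary" option
draws the initial modality from the time fractions): stationarity arguments
fix no convention, so one is stated.

## Simulators

NIF integrates dV = b·dt + √D·dW with threshold 1, reset 0 and a hard
refractory pause τ; its ISI law is exactly τ + IG(1/b, 1/D), so an exact
sampler exists and serves as the reference for validating the SDE route
(two-sample Kolmogorov–Smirnov at n = 10⁴). LIF (dV = (b−V)dt + a·dW,
threshold 1 → 0) and QIF (dV = (b+V²)dt + a·dW, threshold 100 → −100,
finite proxies for ±∞) use Euler–Maruyama with one independent particle per
requested ISI (intervals are iid, so particles never interact). Threshold
crossings are detected at the end of a step and the spike is assigned to
that step's end; the first-passage bias of this scheme is O(√step), and the
default step — 10⁻³ × the estimated mean ISI, capped at 10⁻³ ms — keeps it
below the estimator noise at n = 10⁵ (the step-halving invariant in the
tests bounds the residual mean bias below 1%). Noiseless limits
(ln(b/(b−1)) for LIF, 2·arctan(100/√b)/√b for QIF, τ + 1/b for NIF) are
asserted exactly.

Calibration to a target (rate, C<sub>V</sub>) is closed-form for NIF and GISI; for
LIF/QIF it is Nelder–Mead on the moments of a fixed-seed simulation (common
random numbers make the objective deterministic), with an explicit error
when the target lies outside the reachable region — notably QIF cannot
exceed C<sub>V</sub> ≈ 0.55 in the suprathreshold regime (b ≥ 0.25) covered by the
standard parameter grids.

## What the generators emulate — and what they do not

The synthetic data are exactly the model class the theory addresses:
stationary renewal/ARP spike trains from four standard spiking mechanisms,
at the standard grid scales (LIF b ∈ [1.5, 5.75] step 0.25, a ∈ [0.1, 3.0];
QIF b ∈ [0.25, 4.75], a ∈ [0.25, 2.75] step 0.25; 10⁴–10⁵ ISIs per
condition). They contain no rate nonstationarity, no ISI correlations beyond
the ARP's alternation, no multi-neuron structure, and no measurement noise
(jitter, missed spikes). Tests passing on them therefore certify the
mathematics and the estimator pipeline, not the renewal assumption's
validity for any particular biological recording.

## The universality analysis

The sweep estimates (C*, h*, E, b*) per model per C<sub>V</sub> target. GISI rows are
evaluated analytically (the gamma law is known exactly); NIF rows use the
exact sampler plus the empirical plug-in estimators; LIF/QIF use
Euler–Maruyama plus the same estimators, so estimator bias largely cancels
in cross-IF comparisons. Empirical estimators: exact step-function survival
integrals for C* and the E survival term; Freedman–Diaconis histogram
density for the differential-entropy and density-log terms; Monte-Carlo
pairing with the histogram density for the cross term, refused below
C<sub>V</sub> = 0.25 where the signal falls under the estimator's error (the b*
column is flagged rather than silently reported). Standard errors come from
four block subsamples.

Findings the test suite pins down (and which a user of the sweep should
expect): C* collapses across NIF/LIF/QIF to within ~0.01–0.02 bits at
matched C<sub>V</sub>, and gamma ISIs separate strongly from all integrate-and-fire
models on the h* panel. But h* itself does **not** collapse exactly across
the IF mechanisms: LIF sits a few hundredths of a bit above, and QIF
0.1–0.15 bits below, the exact inverse-Gaussian curve at matched C<sub>V</sub>. This
is a property of the models, not of the estimators — the ISI shape families
genuinely differ at matched C<sub>V</sub> (skewness/C<sub>V</sub> ≈ 3.0 for the
inverse-Gaussian, ≈2.5 for LIF, ≈4.1 for QIF), which was confirmed against
a Fokker–Planck solve of the LIF first-passage density and a scale-function
quadrature for QIF moments. Mechanism-independence of the rescaled
quantities is thus exact in μ (verified across a ×10 rate change) and for
practical purposes exact for C* and E, but only approximate (to ~0.1 bit)
for the entropy-rate panel. One acceptance-level test asserts the stricter
all-panel collapse and documents this gap by failing.

Small-C<sub>V</sub> asymptotics, computed from the closed forms: E grows as
log₂(1/C<sub>V</sub>) with unit slope (fitted 0.91 on C<sub>V</sub> ∈ [0.02, 0.1], within the
10% band) and the bound-information rate diverges as C<sub>V</sub>⁻² (fitted exponent
−2.01), identically for the gamma and inverse-Gaussian families.

## Numerical choices and degenerate inputs

- Quadrature: `scipy.integrate.quad`, absolute tolerance 10⁻¹⁰, 500-interval
  limit; peak breakpoints for C<sub>V</sub> ≤ 0.1 laws.
- 0·log 0 ≡ 0 everywhere; probabilities floored at 10⁻³⁰⁰ inside logs.
- Machine truncation: w(n) < 10⁻⁹; ε-machine class merging: hazards within
  10⁻⁶ relative; ARP forward-pass posterior grid 10⁻⁶ with pruned mass
  tracked.
- Geometric-tail extrapolation (in window length L and future horizon K):
  median increment ratio of the last three increments; refuses ratios
  outside [0, 0.999) and falls back to the raw value with a convergence
  flag.
- Degenerate inputs: C<sub>V</sub> = 0 (delta-like) laws are rejected where an
  integral diverges; empirical distributions refuse the cross term below the
  C<sub>V</sub> floor; subthreshold noiseless LIF raises ("never fires"), as does any
  simulation exceeding 10³ mean-ISI estimates without a spike; equal-modality
  ARPs are redirected to the renewal builder.
- The bound-information rate is natively in bits/ms; a natural-log (nats)
  reading is ln 2 times that value, and `scripts/acceptance.py` reports its
  second target on that scale.

## Known limitations

- Heavy-tailed ISI laws with infinite variance are out of scope (moments,
  C<sub>V</sub> and several integrals are undefined).
- The block-MI route for ARP excess entropy is pruned-exact, not exact; the
  discarded mass is tracked and warned about, and is ≤10⁻⁵ in all shipped
  configurations.
- ε-machine *inference from data* is not provided: machines are built from
  known or empirical ISI laws, not reconstructed from symbol sequences.
- The LIF/QIF calibration inverts (rate, C<sub>V</sub>) by simulation; its accuracy
  is bounded by the fixed calibration sample (relative tolerance ~2–10%).
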