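# Methods

This note documents the model, the numerical choices, and the limits of
what the simulations establish. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script.

## The DOPO-pair neuron

A degenerate optical parametric oscillator locks its phase to 0 or π
relative to the pump, so its in-phase amplitude is a signed real
variable. Two DOPOs (v, w) coupled antisymmetrically
(J_vw·J_wv < 0) form one neuron:

    dv/dt = P v − v³ + J_vw w + I_ext
    dw/dt = P w − w³ + J_wv v

with pump-above-threshold P = −1 + p. The antisymmetric coupling makes
(v, w) rotate at ω₀ = √(−J_vw·J_wv); one full turn of
θ = arg(v + iw) is a spike. The model is odd under
(v, w) → (−v, −w) when I_ext = 0 (phase bistability), so neuron
properties are sign-independent.

Units: the defaults J_vw = −1, J_wv = +1 set ω₀ = 1, and all
dimensionless ("tilde") quantities P̃ = P/ω₀, Ĩ_ext = I_ext/ω₀^{3/2},
J̃_k = J_k/ω₀ equal the raw ones. The sign choice (J_vw negative) makes
θ rotate in the +direction so the Cartesian and polar models agree
without a mirror transformation. Time is measured in 1/ω₀.

## Excitability classes and the frequency law

Writing √R·e^{iθ} = v + iw, the uncoupled neuron obeys

    dθ/dt = ω₀ + (R/4)·sin 4θ
    dR/dt = 2PR − (R²/2)(cos 4θ + 3).

Quasi-statically (dR/dt = 0, angular average) the squared amplitude is
R ≈ (2P/π)∫dθ/(3 + cos 4θ) = √2·P, giving the phase-only equation
dθ/dt = ω₀ + (P/√8)·sin 4θ and the spiking frequency

    ω(P) = ω₀·√(1 − P̃²/8),   0 ≤ P̃ ≤ √8.

* At P = 0 the origin changes from stable to unstable focus
  (eigenvalues P ± iω₀): an Andronov–Hopf bifurcation. Firing starts at
  the finite frequency ω₀ — class-II excitability.
* At P̃ = √8 the phase equation acquires fixed points (four saddle-node
  pairs on the cycle, by the sin 4θ symmetry): a saddle-node bifurcation
  on a limit cycle. The period diverges and firing stops — class-I.

Accuracy: the phase-only reduction reproduces the closed form to 0.1%
everywhere on P̃ ∈ [0.5, 2.5]. The full Cartesian model, however,
deviates from the closed form increasingly near the SNLC edge: measured
rotation frequencies are ≈0.5% low at P̃ = 0.5, 2% at 1.0, 4% at 1.5,
6.7% at 2.0 and ~10% at 2.5 (cross-checked with an independent
adaptive integrator to <0.1%). This is a property of the quasi-static
√2·P amplitude approximation, not of the integrator; the package
exposes both the closed form and measured frequencies and forces
neither to match the other. The full-model SNLC edge itself sits very
close to √8 (the zero-bias frequency scan ceases spiking between
P̃ = 2.67 and 2.83 at the default grid).

## Numerical integration

Fixed-step classical 4th-order Runge–Kutta (explicit Euler available),
default dt = 10⁻² (in 1/ω₀); the ODEs are smooth and non-stiff, and a
fixed step keeps runs exactly reproducible. Endpoint convergence is
verified at 4th order. Divergence (possible with absurd steps) is
caught by a finiteness check at every recorded sample and reported with
a step-size diagnostic.

Initial conditions emulate growth from amplified vacuum noise:
i.i.d. zero-mean Gaussians of amplitude 10⁻³, one substream per neuron
(`default_rng([seed, i])`) so an uncoupled n-neuron run equals n
independent single-neuron runs. No stochastic term acts during
integration — the equations are deterministic; all trial-to-trial
variability enters through the initial state.

The polar integrator floors R at 10⁻¹² (the phase of an empty
oscillator is undefined, not singular) and recomputes the amplitude
ratios ε_ij = √(R_j/R_i) every step. For all-to-all uniform coupling
both polar and Kuramoto simulators use the mean-field O(n) form of the
coupling sums.

The experimental "cavity circulation" has no stated correspondence to
model time; the reporting window (4 recorded samples by default for the
phase-increment observable) is a declared convention, not a physical
fact.

## Spike detection and firing rates

A spike is one full 2π advance of the unwrapped phase, timestamped by
linear interpolation; the 4-fold sin 4θ symmetry of the potential makes
quarter-turn definitions ambiguous, so the full revolution is used and
the detector tag is recorded with every spike train. Crossings with
R < 0.05 are discarded: a subthreshold decaying focus winds in phase at
ω₀ but is noise, not spiking (steady spiking has R ≈ √2·P, far above
the gate for any relevant pump). An amplitude-peak detector (local
maxima of |v|) is available as a cross-check; note it fires on both
polarities, twice per rotation. Rates are angular
(2π × revolutions/time), directly comparable to ω̃. Consequence of the
gate: in pump-ramp runs the first detected spike lags the P̃ = 0
crossing by the amplification time from noise level (ln(R_gate/R₀)
divided by 2P̄), not because of a subthreshold-firing artifact.

## Clustered synchronization and self-tuning

The clustered ensemble follows the 4-clusters-of-15 design: all-to-all
coupling inside each cluster, encoded on both DOPOs (γ = γ′ = J_k), and
sparse inter-cluster links. The text does not fix the inter-cluster
topology or the per-neuron pumps, so both are explicit, seeded
configuration: by default each cluster pair gets 2 random edges at 1×
strength, and cluster pumps are evenly spaced over
center ± 0.15 with centers (0.5, 1.0, 1.5, 2.0) — ascending pump means
clusters A–D have descending intrinsic firing rates through ω(P).

Mechanism (all measured by the suite, seeds fixed): synchronization
raises the effective pump of a cluster member by r(N−1)J_k (mean-field,
ε_ij ≈ 1), pushing neurons toward — and eventually past — the class-I
edge. At J̃_k = 0.025 every cluster's internal rate spread collapses
below 5% of its mean while cluster means stay distinct; the ensemble
mean rate falls monotonically over J̃_k ∈ {0, 0.025, 0.05, 0.075}; at
0.075 the slowest cluster is pushed beyond the √8 edge entirely
(renormalized pump ≈ 2.15 + 1.05 > √8) and stops firing, and the global
order parameter intermittently exceeds 0.9. Phase-increment traces show
the class-I signature at strong coupling: a growing fraction of windows
with near-zero phase advance (stalling at the nascent fixed points).

## Ising annealing

Encoding: instance weights J_ij enter only the v-equations, bias zero,
spins read out as σ_i = sign(v_i) (ties to +1). With
E_Ising = −Σ_{i<j} J_ij σ_i σ_j and E_loc,i = −Σ_j J_ij σ_i σ_j
(so E_Ising = ½ΣE_loc), averaging the coupling term of dR/dt over the
fast rotation gives the renormalized pump

    P′_i = P₀(t) − ½·γ·Σ_j J_ij ε_ij cos(θ_i − θ_j) ≈ P₀(t) − ½·J_k·E_loc,i

for γ = +J_k. The sign matters: γ = +J_k makes low-local-energy
(stable) neurons see a higher effective pump, cross the class-I edge
sooner, and freeze, while unstable neurons keep spiking and flipping —
a selective spin-flip mechanism akin to extremal optimization. The
opposite sign demonstrably anneals toward the energy *maximum* (a
2-spin ferromagnetic pair freezes anti-aligned in 20/20 seeded trials),
which is why this package wires the encoding with γ = +J_k. The
mean-field coefficient from ε_ij ≈ 1 alone is 1 rather than ½; the ½
arises from the cos θ_i cos θ_j → ½cos(θ_i − θ_j) average. Both forms
are exposed (`renormalized_pump`, `renormalized_pump_ising`).

Schedule: node-independent pump ramped linearly, default P̃ from −0.5
(below threshold: only noise) to 3.2 (beyond √8: dynamics freeze into a
readable state) over 500/ω₀. The solver output is the best energy seen
anywhere along the recorded trace, matching how energy trajectories are
monitored; the final configuration and per-neuron firing counts are
reported alongside. Batches derive trial seeds as base_seed + index and
report a binomial 95% CI on the success probability. An exhaustive
oracle (2^{n−1} enumeration, global flip symmetry halved, guarded at
n ≤ 24) provides exact reference energies.

Measured behaviour at the scaled benchmark (n = 16, density 0.5, ±1
weights, 20 trials): the ground state is reached in 100% of trials at
all of J̃_k ∈ {0.083, 0.167, 0.25}, and the firing-count/local-energy
rank correlation is strongly positive (median Spearman ≈ 0.6–0.75) at
all three couplings. The weak-coupling decorrelation expected from the
150-spin regime only appears at genuinely weak coupling here
(median ≈ −0.1 at J̃_k ≈ 0.01–0.03, where the self-tuning pump shift
½J_k·E_loc becomes negligible): at n = 16 the nominal "weak" 0.083 is
already strong relative to the instance. A green annealing test at this
size therefore establishes mechanism and soundness, not hardware-scale
performance.

## Synthetic instances

Random Ising instances are Erdős–Rényi: each of the C(n,2) edges is
present independently with the target density, weights ±1 equiprobable
(the standard frustrated spin-glass family; real-valued uniform weights
available), symmetric with zero diagonal, fully reproducible from the
seed. What they do not emulate: the specific unpublished 150-spin
benchmark, any structured/planted instances, and weight distributions
beyond the two schemes.

## Known limitations

* No optics: pump depletion, gain saturation, squeezing, cavity loss
  and the quadrature components are outside the model (the quadratures
  are negligible above threshold).
* Coupling acts continuously; the discrete measurement-and-feedback
  round trips of the experimental apparatus are not emulated. An
  optional 8-bit weight quantization mirrors the hardware's resolution
  but is off by default.
* Bifurcation boundaries come from grid classification and bisection,
  not numerical continuation; degenerate non-hyperbolic cases report a
  "marginal" tag (|Re λ| < 10⁻⁹) rather than a refined normal form.
* Phase-diagram line scans reproduce the qualitative tomography
  (sudden class-II onset, gradual class-I cessation); exact experimental
  scan coordinates are not published and are not asserted.
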