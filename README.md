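# doponet

Simulator for spiking neural networks built from paired degenerate
optical parametric oscillators (DOPOs) — photonic neurons whose spiking
mode can be switched between Hodgkin's class-I and class-II excitability
by the optical pump, and whose collective dynamics implement a
self-tuning annealing heuristic for Ising combinatorial optimization.

## Who this is for

Researchers in neuromorphic photonics and nonlinear dynamics who want a
software model of coupled-DOPO spiking networks: single-neuron
bifurcation analysis, Kuramoto-style cluster synchronization
experiments, and pump-ramp Ising annealing, without any optics hardware.

## The model

Each neuron is a pair of DOPO amplitudes (v, w) with antisymmetric
internal coupling:

    dv_i/dt = P_i v_i − v_i³ + J_vw w_i + γ  Σ_j J_ij v_j + I_ext
    dw_i/dt = P_i w_i − w_i³ + J_wv v_i + γ′ Σ_j J_ij w_j

where P = −1 + p is the pump above threshold and
ω₀ = √(−J_vw·J_wv) the natural rotation frequency (defaults J_vw = −1,
J_wv = +1, so ω₀ = 1 and all tilde quantities P̃ = P/ω₀,
Ĩ_ext = I_ext/ω₀^(3/2) coincide with the raw ones). One full rotation of
θ = arg(v + iw) is one spike.

Key laws (all verified by the test suite):

* steady squared amplitude R = v² + w² ≈ √2·P,
* spiking frequency ω(P) = ω₀√(1 − P̃²/8) for 0 ≤ P̃ ≤ √8,
* Andronov–Hopf bifurcation at P = 0 (class-II onset: finite frequency),
* saddle-node-on-limit-cycle at P̃ = √8 (class-I cessation: ω → 0),
* synchronized clusters renormalize the pump, P′ = P + r(N−1)J_k, where
  r = |N⁻¹Σ e^{iθ_j}| is the Kuramoto order parameter,
* in the Ising encoding (weights on v only, sign(v) read out as spins),
  P′_i = P₀(t) − ½J_k·E_loc,i: energetically unstable neurons keep
  spiking and flipping, stable ones freeze first.

## Worked example

```python
import doponet as dn

print("SNLC edge P* =", round(dn.snlc_threshold(), 6))
for p in (0.5, 1.0, 2.0):
    params = dn.NeuronParams.from_tilde([p])
    cfg = dn.SimulationConfig(duration=300.0, record_stride=2, seed=2)
    traj = dn.simulate(params, dn.NetworkCoupling.uncoupled(1), cfg)
    rate = dn.detect_spikes(dn.to_polar(traj.window(75.0))).rates[0]
    print(f"P~={p}: measured omega~={rate:.4f}  closed form={dn.omega_closed_form(p):.4f}")

inst = dn.generate_random_instance(12, 0.5, "pm1", seed=0)
oracle = dn.brute_force_ground_state(inst)
batch = dn.run_trials(inst, dn.AnnealSchedule(j_k=0.25), n_trials=5,
                      base_seed=1, reference_energy=oracle.min_energy)
print("ground energy =", oracle.min_energy,
      " best found =", batch.best_energy,
      " success =", batch.success_probability)
```

prints

```
SNLC edge P* = 2.828427
P~=0.5: measured omega~=0.9792  closed form=0.9843
P~=1.0: measured omega~=0.9171  closed form=0.9354
P~=2.0: measured omega~=0.6597  closed form=0.7071
ground energy = -16.0  best found = -16.0  success = 1.0
```

The SNLC edge found by bisection equals √8 ≈ 2.8284: above that pump no
spiking survives. Measured frequencies track the closed form closely at
small pump and fall a few percent below it as the pump approaches the
edge — the √2·P amplitude law behind the closed form is quasi-static
(see `docs/methods.md`). The 12-spin anneal reaches the exact
brute-force ground energy in all five seeded trials.

## Command line

```
doponet simulate        --config cfg.yaml --seed 1 --outdir out/
doponet phase-diagram   --config cfg.yaml --outdir out/
doponet sync-experiment --config cfg.yaml --outdir out/
doponet gen-instance instance.txt --seed 3
doponet anneal instance.txt --config cfg.yaml --outdir out/
doponet stability       --outdir out/
```

Configs are strict YAML (unknown keys are errors); every command writes
its resolved config and a manifest next to its outputs, and identical
config + seed reproduce identical files. Ising instances use a plain
edge-list text format (`n m` header, then `i j w` lines, 1-based,
`#` comments allowed).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch with the given
seed: the √2·P quadrature cross-check, the √8 spiking edge by bisection,
a zero-bias phase-diagram scan with AH/SNLC boundary detection, a
clustered synchronization run, and a seeded annealing batch verified
against the brute-force oracle, then writes the JSON results file.
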