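# gardpop

Stochastic simulator for populations of multicomponent lipid vesicles
competing for a finite, mass-conserved pool of monomers — a protocell model
in the GARD (Graded Autocatalysis Replication Domain) family, with an
analysis layer for the statistics such simulations are judged by.

## The problem

In the "Lipid World" picture of abiogenesis, amphiphile assemblies carry
heritable *compositional* information: the mix of lipids in a vesicle
modulates how fast each lipid species enters and leaves it, so a
composition can bias its own propagation across growth–division cycles.
`gardpop` simulates a whole population of such vesicles from a single seed:
vesicles grow by monomer exchange with a shared environment holding a fixed
total number of molecules, divide by random assortment when they reach a
size threshold, and — because the pool is finite — eventually compete with
each other for material. The package is for researchers who want to study
when such a purely lipidic system shows evolution-like behavior
(selection, heritable variation, competition) and what is lost when either
the compositional feedback or the molecular heterogeneity is removed.

## The model

The default chemistry is a catalog of 141 lipid species: four phospholipid
classes (PC, PE, PS, SM) on a grid of 5 acyl-chain lengths × 7 unsaturation
levels, plus cholesterol (CHOL). Each species carries base rate constants
`k_f` (entry, M⁻¹s⁻¹) and `k_b` (exit, s⁻¹), a head-group area, a charge
(PS = −1) and a complex-formation index CF1 (CHOL = −1, SM = +3).

For vesicle *v* and species *i* the adjusted rates are

```
kf_adj(i,v) = k_f(i) · C_i · (A_v / A_ref) · F(i,v)
kb_adj(i,v) = k_b(i) / F(i,v)
```

where `C_i` is the species' free monomer concentration, `A_v` the vesicle's
surface area, and `F` a composition-compatibility factor built from the
vesicle's average properties (chain length, unsaturation, charge,
curvature, CF1):

```
F = exp(−α_L |len_i − ⟨len⟩|) · exp(−α_U |u_i − ⟨u⟩|)
  · exp(−α_q q_i Q) · exp(−α_c (c_i − K) K) · exp(+α_cf1 CF1_i ⟨CF1⟩)
```

Compatible lipids enter faster *and* leave slower — the autocatalytic loop
that makes compositions heritable. **Full kinetics** uses this `F`;
**invariant kinetics** (the control) fixes `F ≡ 1`. Dynamics are advanced
by fixed-step tau-leaping (Poisson entries capped by the shared pool,
binomial exits), division splits every molecule of a 20,000-lipid vesicle
binomially between two progeny, and the molecule total
(pool + all vesicles) is an exact integer invariant.

## Worked example

```python
from gardpop import generate_default_catalog, run
from gardpop.simulate import toy_config
from gardpop.analysis import time_to_mean_generation

catalog = generate_default_catalog()
for mode in ("full", "invariant"):
    traj = run(toy_config(mode, rng_seed=1), catalog)
    t6 = time_to_mean_generation(traj, 6.0)
    print(f"{mode:9s}: mean generation 6 reached at t = {t6:.2f} s; "
          f"{traj.final.n_vesicles} vesicles alive")
```

prints

```
full     : mean generation 6 reached at t = 1.18 s; 64 vesicles alive
invariant: mean generation 6 reached at t = 3.13 s; 64 vesicles alive
```

— with composition-modified kinetics the population replicates ~2.6× faster
than the invariant control under identical resources. Continuing the full-
kinetics run past depletion to its steady state (same seed,
`stop_generation=1e9, t_max=60`) yields a peak shrinking fraction of 0.72
during the competition phase (a majority of vesicles losing material to a
better-adapted minority), mean class mole fractions
`{PC: 0.210, PE: 0.206, PS: 0.203, SM: 0.223, CHOL: 0.158}` — near the 0.2
environmental ratio — and an across-vesicle SD of class fractions of 0.111,
an order of magnitude above the invariant control (~0.010).

The `gardpop` command exposes the same machinery from a shell:

```
gardpop simulate --mode full --seed 1 --out out/        # SQLite + CSV trajectory
gardpop analyze out/trajectory.db --at 51 --out report/ # correlations, distributions, PCA
gardpop matrix --out matrix/                            # knockout scenario table
```

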