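# Methods

## Model

A run tracks an integer number of free monomers of each lipid species in a
fixed solution volume, plus a population of vesicles, each an integer
composition vector over the species catalog. The volume follows from the
configured budget and total concentration, `V = N_total / (N_A · C_total)`;
with the defaults (4.096 × 10⁷ molecules at 1.41 × 10⁻⁸ M) this is
≈ 4.82 × 10⁻⁹ L. Molecules are neither created nor destroyed: every step
and every division conserves the total exactly, in integer arithmetic, and
the trajectory recorder asserts this at every snapshot.

Per vesicle *v* and species *i*, entry is a Poisson process with intensity
`k_f(i) · C_i · (A_v/A_ref) · F(i,v)` and exit of each bound molecule is a
first-order process with rate `k_b(i) / F(i,v)`. The area factor makes
entry proportional to the membrane available for insertion; `A_ref` is the
area of a seed-sized vesicle of the pool's average composition, so a
seed-sized vesicle has an area scale of 1. `F` is the
composition-compatibility factor described in the README: exponential
penalty terms for chain-length and unsaturation mismatch with the vesicle's
averages, and signed bilinear terms for charge (like-charge repulsion),
curvature (relaxation: lipids that reduce a curved vesicle's curvature are
favored) and CF1 complex formation (SM self-association, SM–CHOL
antagonism). One shared factor promotes entry and suppresses exit — the
"direct effect" of acyl packing: lipids compatible with the membrane both
enter more readily and leave it less readily.

Assumptions worth stating plainly: vesicles are well-mixed bags with no
spatial structure, leaflets or osmotic state; "curvature", "charge" and
"CF1" are scalar composition functionals, not geometric quantities;
division is triggered purely by size (20,000 lipids) and assorts every
molecule independently with probability 1/2 per daughter; the environment
is a single well-mixed compartment.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `total_molecules` | 4.096 × 10⁷ | molecules | budget for 4096 vesicles of 10⁴ lipids |
| `total_conc` | 1.41 × 10⁻⁸ | M | sets the (fixed) volume |
| `seed_vesicle_size` | 10,000 | lipids | half the division threshold |
| `division_threshold` | 20,000 | lipids | size-doubling division |
| `dt` | 0.02 (full scale), 0.005 (toy) | s | see *Numerical choices* |
| `t_max` | 300 | s | stop bound; see *Limitations* |
| `stop_generation` | 12 | — | target population age |
| `k_f` per class | PC 1.0, PE 0.625, PS 0.625, SM 0.75, CHOL 4.0 (× 10¹¹) | M⁻¹s⁻¹ | CHOL fastest in; saturated long chains insert faster (±4 %/carbon, −3 %/double bond) |
| `k_b` per class | PC 0.010, PE 0.0125, PS 0.0125, SM 0.025, CHOL 0.020 | s⁻¹ | SM fastest out; exits small enough that the pool is deeply consumed |
| `α_L, α_U` | 0.1 /carbon, 0.05 /bond | — | mild packing-mismatch penalties |
| `α_q` | 0.5 | — | like-charge repulsion |
| `α_c` | +1.5 | — | curvature relaxation (CHOL loaded early, shed later) |
| `α_cf1` | 2.5 | — | complex formation; the main accelerant of full kinetics |
| factor clamp | [10⁻⁶, 10⁶] | — | numerical safety only |

The `k_f` scale is an *effective per-vesicle* association constant at the
reference area (a vesicle offers ~10⁴ insertion sites), chosen together
with `k_b` so that: the invariant-mode population consumes ≳ 95 % of the
pool at steady state (which pins the class mole fractions to the
environment's ratios), and toy-scale runs resolve their full dynamics in
tens of simulated seconds. The α values were fixed once, by pilot
exploration, to place the full-kinetics mode in the qualitative regime the
model family is known for — faster replication than the invariant control,
a majority-shrinking competition phase after pool depletion, and
persistently heterogeneous compositions — and are exposed in
`KineticsConfig` so other regimes can be explored without touching the
stepper.

## What the default catalog emulates — and what it does not

The catalog generator emits deterministic, biologically plausible grids
(chain lengths 14–22, unsaturation 0–6, single CHOL with effective packing
length 18) with per-class constants. It stands in for a table of measured
per-species lipid–vesicle kinetics; it reproduces class-level orderings
(CHOL's fast entry, SM's fast exit) but not any particular measured values.
Absolute times and correlations produced with this catalog therefore
characterize *this* parameterization, not any specific experimental lipid
set; a replacement table can be dropped in as CSV via `load_catalog`
without code changes. Likewise the environment initializer splits the
budget equally across classes (uniformly within a class) — the choice that
makes "fractions converge to the environment's ratios" a sharp ~0.2
prediction — whereas a real monomer bath would be skewed.

Consequently, passing tests show that the *mechanisms* (finite-resource
competition, compositional inheritance, mode contrasts) behave as designed;
they do not validate rate values against laboratory kinetics.

## Numerical choices

* **Tau-leaping.** Fixed-step: entries ~ Poisson, exits ~
  Binomial(n, 1 − e^(−kb_adj·dt)) per (vesicle, species); division and
  death are resolved at step boundaries (a vesicle crossing the threshold
  within a step divides once at its end; an extreme-overshoot child simply
  divides again the next step). `dt` is set so per-lipid rates times `dt`
  stay at the few-percent level: 0.02 s at full scale, 0.005 s for toy
  configurations whose per-lipid rates are ~10× higher. A step-halving test
  checks that ensemble summaries are unchanged.
* **Pool contention.** If the summed Poisson demand for a species exceeds
  its free count, allocations are scaled proportionally and rounded by
  largest remainder with a stable sort — deterministic, integer-exact, and
  free of vesicle-order artifacts. Poisson intensities are pre-clamped at
  `4·free + 1000`, which only touches draws the allocation step would cap
  anyway.
* **Seeding.** The seed vesicle is a multivariate-hypergeometric draw from
  the pool (the finite-pool form of proportional sampling), debited
  exactly.
* **Snapshots.** After a snapshot at iteration *i*, the next follows in
  `min(5 · 2^⌊i/50⌋, 50)` iterations; a final snapshot is always forced at
  termination. Full per-species compositions are stored while the
  population is ≤ 256 vesicles ("auto" policy); class counts, properties
  and totals are stored for every vesicle always, and every downstream
  statistic consumes only those.
* **Degenerate inputs.** Properties of an empty vesicle raise; a
  zero-variance predictor in the correlation report yields `NaN` with a
  diagnostic note rather than a spurious coefficient; a mean-generation
  target never reached reports `None`.
* **Determinism.** One `numpy` Generator seeded from `rng_seed` drives
  everything; identical seeds give bit-identical trajectories, and
  invariant mode is bit-identical to full mode with all α = 0.

## Design choices at genuinely open points

* **Exit coupling.** Exit rates are divided by the same factor that
  multiplies entry. A single factor is the smallest model that yields both
  preferential uptake and retention; the alternatives (entry-only or
  exit-only modification) are reachable by config but are not the default.
* **Knockouts** keep the total budget and redistribute it over the
  remaining classes, so scenarios compare at equal resources.
* **Death.** A vesicle that reaches zero lipids is removed and logged; the
  division threshold guarantees it can never be a division product.
* **Curvature coefficients** (CHOL 1.0, SM 0.5, PS 0.3, PC/PE 0) encode
  only the intended ordering — curvature tracks CHOL most closely — and are
  config-overridable; their magnitudes are free parameters.
* **Toy scale.** Tests and desk experiments use a ~200× reduced budget
  (2 × 10⁵ molecules, 1,000-lipid seeds, division at 2,000) at identical
  concentrations, which preserves per-molecule kinetics while making a
  complete growth–competition–steady-state arc take seconds of wall time.

## Known limitations

* **Population age at full scale.** Because daughters inherit half of a
  20,000-lipid parent almost exactly, full-budget populations divide in
  near-synchronized waves, and relative composition noise at 10⁴ lipids is
  too small to break the symmetry. The twelfth wave would require the
  entire budget to sit in 2048 vesicles of exactly 20,000 lipids at once,
  so default full-scale runs plateau at a mean generation of ~11 and
  terminate at `t_max` (300 s) with ~2048 living vesicles. Toy-scale
  populations, whose relative noise is ~3× larger, do cross their
  generation targets during growth. Raising heterogeneity (or loading a
  catalog with stronger per-species contrasts) is the lever for pushing
  full-scale runs past the plateau.
* **Mode contrast is qualitative.** The ~2–3× full-vs-invariant speed
  ratio, the competition hump and the variance gap are robust directional
  features under the default chemistry; their magnitudes are not calibrated
  to any measured lipid set.
* **No environment exchange.** The pool has no inflow, outflow,
  hydration–dehydration cycling or thermal forcing; these are outside the
  current scope.
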