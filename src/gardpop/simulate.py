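"""Stochastic population stepper: all vesicles sharing one finite monomer pool.

The update scheme is fixed-step tau-leaping.  Within one step of length ``dt``
every (vesicle, species) pair draws

* entries ~ Poisson(kf_adj * dt), capped by the free pool — when the summed
  demand for a species exceeds its free monomers the draws are scaled
  proportionally (largest-remainder rounding), so no vesicle order artifact is
  introduced and the pool never goes negative;
* exits ~ Binomial(counts, 1 - exp(-kb_adj * dt)).

After the fluxes are applied, vesicles that reached zero lipids are removed
("death"), and any vesicle at/above the division threshold divides once by
binomial assortment.  The combined molecule count of pool plus vesicles is an
exact integer invariant of every step.

Snapshots of every vesicle and the pool are recorded on a geometric schedule:
after a snapshot at iteration ``i`` the next one is ``min(base * 2^(i//50),
cap)`` iterations later, so early dynamics are densely sampled and long runs
stay bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .catalog import Catalog
from .environment import EnvironmentState, apply_flux, init_environment
from .kinetics import KineticsConfig, modification_matrix
from .vesicle import properties_matrix


class ConservationError(RuntimeError):
    """Fatal: the pool + vesicle molecule total drifted from the budget."""


@dataclass(frozen=True)
class SimulationConfig:
    mode: str = "full"
    division_threshold: int = 20_000
    total_molecules: int = 40_960_000
    total_conc: float = 1.41e-8  # M
    seed_vesicle_size: int = 10_000
    dt: float = 0.02             # s (full-scale per-lipid rates ~0.1-0.7/s)
    t_max: float = 300.0         # s
    stop_generation: float = 12.0
    rng_seed: int = 0
    snapshot_base: int = 5
    snapshot_cap: int = 50
    kinetics: KineticsConfig | None = None
    store_compositions: str = "auto"   # "auto" | "always" | "never"
    #: in "auto" mode, full per-species compositions are stored while the
    #: population is at most this many vesicles
    composition_auto_limit: int = 256

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.division_threshold <= self.seed_vesicle_size:
            raise ValueError("division_threshold must exceed seed_vesicle_size")
        if self.store_compositions not in ("auto", "always", "never"):
            raise ValueError("store_compositions must be auto/always/never")
        if self.mode not in ("full", "invariant"):
            raise ValueError("mode must be 'full' or 'invariant'")
        if self.kinetics is not None and self.kinetics.mode != self.mode:
            raise ValueError("cfg.mode and cfg.kinetics.mode disagree")

    def resolved_kinetics(self) -> KineticsConfig:
        return self.kinetics if self.kinetics is not None else KineticsConfig(mode=self.mode)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        kin = d.pop("kinetics", None)
        if isinstance(kin, dict):
            kin = KineticsConfig(**{**{"mode": d.get("mode", "full")}, **kin})
        return cls(kinetics=kin, **d)


def snapshot_interval(i: int, base: int = 5, cap: int = 50) -> int:
    """Iterations between stored snapshots: ``min(base * 2^(i // 50), cap)``."""
    return int(min(base * 2 ** (i // 50), cap))


@dataclass
class Population:
    """Structure-of-arrays container for all living vesicles."""

    vesicle_id: np.ndarray   # int64 (V,)
    parent_id: np.ndarray    # int64 (V,), -1 for the seed
    generation: np.ndarray   # int64 (V,)
    birth_time: np.ndarray   # float (V,)
    counts: np.ndarray       # int64 (V, S)
    next_id: int
    division_log: list[tuple[float, int, int, int]] = field(default_factory=list)
    death_log: list[tuple[float, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.vesicle_id)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def mean_generation(self) -> float:
        return float(self.generation.mean()) if len(self) else float("nan")


@dataclass
class Snapshot:
    """State of every living vesicle and the pool at one recorded iteration."""

    iteration: int
    time: float
    vesicle_id: np.ndarray
    parent_id: np.ndarray
    generation: np.ndarray
    birth_time: np.ndarray
    total: np.ndarray
    class_counts: np.ndarray  # (V, n_classes) in catalog.classes order
    properties: np.ndarray    # (V, 6) in PROPERTY_NAMES order
    env_free: np.ndarray      # (S,)
    counts: np.ndarray | None = None  # (V, S) when composition storage is on

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicle_id)


@dataclass
class Trajectory:
    """Everything a run produced: snapshots, lineage events, and metadata."""

    config: SimulationConfig
    catalog: Catalog
    snapshots: list[Snapshot]
    divisions: list[tuple[float, int, int, int]]
    deaths: list[tuple[float, int]]
    volume: float
    area_ref: float
    stop_reason: str

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def seed_population(
    cfg: SimulationConfig,
    catalog: Catalog,
    env: EnvironmentState,
    rng: np.random.Generator,
) -> tuple[Population, EnvironmentState]:
    """Draw the seed vesicle from the pool and debit it.

    The seed's composition is a multivariate-hypergeometric draw of
    ``seed_vesicle_size`` molecules from the pool's current counts (sampling
    the pool without replacement, so conservation is exact by construction).
    """
    n = cfg.seed_vesicle_size
    if env.free_counts.sum() < n:
        raise ValueError(
            f"pool holds {env.free_counts.sum()} molecules, cannot seed {n}"
        )
    seed_counts = rng.multivariate_hypergeometric(env.free_counts, n).astype(np.int64)
    env = apply_flux(env, -seed_counts)
    pop = Population(
        vesicle_id=np.array([0], dtype=np.int64),
        parent_id=np.array([-1], dtype=np.int64),
        generation=np.array([0], dtype=np.int64),
        birth_time=np.array([0.0]),
        counts=seed_counts[None, :].copy(),
        next_id=1,
    )
    return pop, env


def _allocate_scarce(entries: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Cap per-species entry demand at the free pool.

    Oversubscribed species are scaled proportionally across vesicles and
    rounded by largest remainder (stable argsort, so deterministic), which
    preserves integer totals without favoring any vesicle ordering.
    """
    demand = entries.sum(axis=0)
    over = np.nonzero(demand > free)[0]
    if over.size == 0:
        return entries
    entries = entries.copy()
    for j in over:
        avail = int(free[j])
        col = entries[:, j]
        if avail == 0:
            entries[:, j] = 0
            continue
        scaled = col * (avail / demand[j])
        base = np.floor(scaled).astype(np.int64)
        short = avail - int(base.sum())
        if short > 0:
            frac = scaled - base
            take = np.argsort(-frac, kind="stable")[:short]
            base[take] += 1
        entries[:, j] = base
    return entries


def step(
    pop: Population,
    env: EnvironmentState,
    catalog: Catalog,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    time: float,
    area_ref: float,
    kcfg: KineticsConfig | None = None,
) -> tuple[Population, EnvironmentState]:
    """Advance every vesicle and the pool by one tau-leap of length ``cfg.dt``.

    Division and death are resolved at the end of the step; a vesicle
    overshooting the threshold within the step divides exactly once.
    """
    if len(pop) == 0:
        return pop, env
    kcfg = kcfg if kcfg is not None else cfg.resolved_kinetics()
    dt = cfg.dt

    props = properties_matrix(pop.counts, catalog)
    factors = modification_matrix(props, catalog, kcfg)
    conc = env.concentrations()
    area_scale = (props[:, 5] / area_ref) ** kcfg.area_exponent

    lam = catalog.kf[None, :] * conc[None, :] * area_scale[:, None] * factors * dt
    # Poisson numerical guard: demand beyond a few times the pool is capped by
    # the allocation below anyway, so clamping lambda there changes nothing.
    lam = np.minimum(lam, 4.0 * env.free_counts[None, :] + 1e3)
    entries = rng.poisson(lam).astype(np.int64)
    entries = _allocate_scarce(entries, env.free_counts)

    p_exit = -np.expm1(-(catalog.kb[None, :] / factors) * dt)
    exits = rng.binomial(pop.counts, p_exit).astype(np.int64)

    pop.counts += entries - exits
    env = apply_flux(env, exits.sum(axis=0) - entries.sum(axis=0))

    t_end = time + dt
    totals = pop.totals

    dead = totals == 0
    if dead.any():
        for vid in pop.vesicle_id[dead]:
            pop.death_log.append((t_end, int(vid)))
        keep = ~dead
        pop.vesicle_id = pop.vesicle_id[keep]
        pop.parent_id = pop.parent_id[keep]
        pop.generation = pop.generation[keep]
        pop.birth_time = pop.birth_time[keep]
        pop.counts = pop.counts[keep]
        totals = totals[keep]

    ready = np.nonzero(totals >= cfg.division_threshold)[0]
    if ready.size:
        child1 = rng.binomial(pop.counts[ready], 0.5).astype(np.int64)
        child2 = pop.counts[ready] - child1
        n_new = ready.size
        ids1 = pop.next_id + np.arange(n_new, dtype=np.int64)
        ids2 = pop.next_id + n_new + np.arange(n_new, dtype=np.int64)
        pop.next_id += 2 * n_new
        for k, r in enumerate(ready):
            pop.division_log.append(
                (t_end, int(pop.vesicle_id[r]), int(ids1[k]), int(ids2[k]))
            )
        parent_ids = pop.vesicle_id[ready].copy()
        # child1 takes the parent's row; child2 rows are appended
        pop.counts[ready] = child1
        pop.vesicle_id[ready] = ids1
        pop.parent_id[ready] = parent_ids
        pop.generation[ready] += 1
        pop.birth_time[ready] = t_end
        pop.vesicle_id = np.concatenate([pop.vesicle_id, ids2])
        pop.parent_id = np.concatenate([pop.parent_id, parent_ids])
        pop.generation = np.concatenate([pop.generation, pop.generation[ready]])
        pop.birth_time = np.concatenate([pop.birth_time, np.full(n_new, t_end)])
        pop.counts = np.concatenate([pop.counts, child2], axis=0)

    return pop, env


def _take_snapshot(
    iteration: int,
    time: float,
    pop: Population,
    env: EnvironmentState,
    catalog: Catalog,
    cfg: SimulationConfig,
) -> Snapshot:
    bound = int(pop.counts.sum())
    if bound + int(env.free_counts.sum()) != env.total_budget:
        raise ConservationError(
            f"iteration {iteration}: pool+vesicles = "
            f"{bound + int(env.free_counts.sum())} != budget {env.total_budget}"
        )
    cls_mat = catalog.class_matrix()  # (C, S) bool
    class_counts = pop.counts @ cls_mat.T.astype(np.int64)
    props = properties_matrix(pop.counts, catalog) if len(pop) else np.zeros((0, 6))
    store = cfg.store_compositions == "always" or (
        cfg.store_compositions == "auto" and len(pop) <= cfg.composition_auto_limit
    )
    return Snapshot(
        iteration=iteration,
        time=time,
        vesicle_id=pop.vesicle_id.copy(),
        parent_id=pop.parent_id.copy(),
        generation=pop.generation.copy(),
        birth_time=pop.birth_time.copy(),
        total=pop.totals.copy(),
        class_counts=class_counts,
        properties=props,
        env_free=env.free_counts.copy(),
        counts=pop.counts.copy() if store else None,
    )


def run(cfg: SimulationConfig, catalog: Catalog) -> Trajectory:
    """Run one complete simulation: seed, step to the stop criterion, record.

    Stops at ``t >= t_max`` or when the population's mean generation reaches
    ``stop_generation``, whichever comes first.  Fully reproducible from
    ``cfg.rng_seed``.
    """
    kcfg = cfg.resolved_kinetics()
    rng = np.random.default_rng(cfg.rng_seed)
    env = init_environment(catalog, cfg.total_molecules, cfg.total_conc)
    # reference area: a seed-sized vesicle of the pool's average composition
    env_frac = env.free_counts / env.free_counts.sum()
    area_ref = cfg.seed_vesicle_size * float(env_frac @ catalog.head_areas)
    pop, env = seed_population(cfg, catalog, env, rng)

    snapshots = [_take_snapshot(0, 0.0, pop, env, catalog, cfg)]
    next_snap = snapshot_interval(0, cfg.snapshot_base, cfg.snapshot_cap)
    i = 0
    t = 0.0
    stop_reason = "t_max"
    while True:
        pop, env = step(pop, env, catalog, cfg, rng, t, area_ref, kcfg)
        i += 1
        t = i * cfg.dt
        if i == next_snap:
            snapshots.append(_take_snapshot(i, t, pop, env, catalog, cfg))
            next_snap = i + snapshot_interval(i, cfg.snapshot_base, cfg.snapshot_cap)
        if len(pop) == 0:
            stop_reason = "extinct"
            break
        if pop.mean_generation() >= cfg.stop_generation:
            stop_reason = "generation"
            break
        if t >= cfg.t_max:
            stop_reason = "t_max"
            break
    if snapshots[-1].iteration != i:
        snapshots.append(_take_snapshot(i, t, pop, env, catalog, cfg))
    return Trajectory(
        config=cfg,
        catalog=catalog,
        snapshots=snapshots,
        divisions=list(pop.division_log),
        deaths=list(pop.death_log),
        volume=env.volume,
        area_ref=area_ref,
        stop_reason=stop_reason,
    )


def toy_config(mode: str = "full", rng_seed: int = 0, **overrides) -> SimulationConfig:
    """A small configuration with the same per-lipid kinetics as the default
    run (same concentrations; budget, seed size and threshold scaled down
    ~200x) for tests and desk-scale experiments."""
    base = dict(
        mode=mode,
        total_molecules=200_000,
        seed_vesicle_size=1_000,
        division_threshold=2_000,
        stop_generation=6.0,
        t_max=400.0,
        dt=0.005,  # toy per-lipid rates are ~10x the full-scale ones
        rng_seed=rng_seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
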