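"""Scenario matrix: replicated runs across modes, knockouts and single lipids.

A *scenario* is a (kinetics mode, catalog variant) pair, e.g. ``full/all``,
``invariant/noCHOL`` or ``full/PC_18:1``.  Each scenario runs ``n``
independent replicates (seeds ``base_seed + k``) and aggregates the time for
the population to reach the target mean generation and the final vesicle
count.  Scenario pairs are compared with Welch's two-sample t-test on the
per-replicate crossing times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import time_to_mean_generation
from .catalog import Catalog, generate_default_catalog, knockout, single_lipid_catalog
from .simulate import SimulationConfig, Trajectory, run

KNOCKOUT_CLASSES = ("CHOL", "PC", "PE", "PS", "SM")
#: single-lipid analogues used in homogeneous-vesicle runs
SINGLE_LIPIDS = ("PC_18:1", "PC_16:0")  # DOPC, DPPC


@dataclass
class ScenarioResult:
    scenario_id: str
    mode: str
    catalog_label: str
    seeds: list[int]
    times_to_target: list[float | None]  # None: replicate never reached target
    final_counts: list[int]
    target_generation: float

    @property
    def replicates(self) -> int:
        return len(self.seeds)

    @property
    def reached(self) -> list[float]:
        return [t for t in self.times_to_target if t is not None]

    @property
    def time_mean(self) -> float | None:
        r = self.reached
        return float(np.mean(r)) if r else None

    @property
    def time_sd(self) -> float | None:
        r = self.reached
        return float(np.std(r, ddof=1)) if len(r) >= 2 else None

    @property
    def count_mean(self) -> float:
        return float(np.mean(self.final_counts))

    @property
    def count_sd(self) -> float | None:
        c = self.final_counts
        return float(np.std(c, ddof=1)) if len(c) >= 2 else None

    def summary_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "formalism": self.mode,
            "lipid_types": self.catalog_label,
            "time_s": self.time_mean,
            "sd": self.time_sd,
            "runs": self.replicates,
            "reached": len(self.reached),
            "final_vesicles_mean": self.count_mean,
            "final_vesicles_sd": self.count_sd,
        }


def resolve_catalog(label: str, base: Catalog | None = None) -> Catalog:
    """``"all"`` -> full catalog; ``"noXX"`` -> class knockout; otherwise a
    species id -> single-lipid catalog."""
    base = base if base is not None else generate_default_catalog()
    if label == "all":
        return base
    if label.startswith("no") and label[2:] in KNOCKOUT_CLASSES:
        return knockout(base, label[2:])
    return single_lipid_catalog(label, base)


def run_scenario(
    mode: str,
    catalog_label: str,
    n_replicates: int,
    base_seed: int,
    cfg_template: SimulationConfig | None = None,
    base_catalog: Catalog | None = None,
    keep_trajectories: bool = False,
) -> ScenarioResult | tuple[ScenarioResult, list[Trajectory]]:
    """Run ``n_replicates`` independent replicates of one scenario."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    cfg_template = cfg_template if cfg_template is not None else SimulationConfig()
    catalog = resolve_catalog(catalog_label, base_catalog)
    times: list[float | None] = []
    counts: list[int] = []
    seeds: list[int] = []
    trajs: list[Trajectory] = []
    for k in range(n_replicates):
        seed = base_seed + k
        kin = cfg_template.kinetics
        if kin is not None:
            kin = replace(kin, mode=mode)
        cfg = replace(cfg_template, mode=mode, rng_seed=seed, kinetics=kin)
        traj = run(cfg, catalog)
        times.append(time_to_mean_generation(traj, cfg.stop_generation))
        counts.append(traj.final.n_vesicles)
        seeds.append(seed)
        if keep_trajectories:
            trajs.append(traj)
    result = ScenarioResult(
        scenario_id=f"{mode}/{catalog_label}",
        mode=mode,
        catalog_label=catalog_label,
        seeds=seeds,
        times_to_target=times,
        final_counts=counts,
        target_generation=cfg_template.stop_generation,
    )
    return (result, trajs) if keep_trajectories else result


@dataclass(frozen=True)
class ComparisonReport:
    scenario_a: str
    scenario_b: str
    statistic: float
    df: float
    p: float


def compare_scenarios(a: ScenarioResult, b: ScenarioResult) -> ComparisonReport:
    """Welch's unequal-variance t-test on the per-replicate crossing times."""
    xa, xb = np.asarray(a.reached, float), np.asarray(b.reached, float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each scenario needs >= 2 replicates that reached target")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: identical constants compare as indistinguishable
        stat, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        dof = float(xa.size + xb.size - 2)
    else:
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        se2a, se2b = va / xa.size, vb / xb.size
        dof = (se2a + se2b) ** 2 / (
            se2a**2 / (xa.size - 1) + se2b**2 / (xb.size - 1)
        )
    return ComparisonReport(a.scenario_id, b.scenario_id, float(stat), float(dof), float(p))


@dataclass
class MatrixConfig:
    """Replicate counts and scale for the full scenario matrix."""

    replicates_all: int = 6
    replicates_knockout: int = 3
    replicates_single: int = 3
    base_seed: int = 1000
    cfg_template: SimulationConfig = field(default_factory=SimulationConfig)
    single_lipids: Sequence[str] = SINGLE_LIPIDS


def full_matrix(mcfg: MatrixConfig) -> tuple[pd.DataFrame, list[ScenarioResult]]:
    """Run {full, invariant} x {all, noCHOL, noPC, noPE, noPS, noSM} plus the
    single-lipid scenarios; return a tidy summary table and all results."""
    results: list[ScenarioResult] = []
    seed = mcfg.base_seed
    for mode in ("full", "invariant"):
        for label in ("all", *(f"no{c}" for c in KNOCKOUT_CLASSES)):
            n = mcfg.replicates_all if label == "all" else mcfg.replicates_knockout
            results.append(
                run_scenario(mode, label, n, seed, mcfg.cfg_template)
            )
            seed += 100
        for sid in mcfg.single_lipids:
            results.append(
                run_scenario(mode, sid, mcfg.replicates_single, seed, mcfg.cfg_template)
            )
            seed += 100
    table = pd.DataFrame([r.summary_row() for r in results])
    return table, results
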