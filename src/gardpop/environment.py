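"""The finite, mass-conserved free-monomer pool shared by all vesicles.

The environment is a fixed volume of solution holding an integer number of
free monomers of each catalog species.  Molecules move between the pool and
vesicles but are never created or destroyed: the sum of free monomers and all
vesicle-bound lipids equals the run's total budget at every instant, as exact
integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23  # mol^-1


@dataclass
class EnvironmentState:
    free_counts: np.ndarray  # non-negative integers per catalog species
    volume: float            # litres, fixed for the whole run
    total_budget: int        # constant: free + vesicle-bound molecules

    def __post_init__(self) -> None:
        self.free_counts = np.asarray(self.free_counts, dtype=np.int64)
        if (self.free_counts < 0).any():
            raise ValueError("free monomer counts must be non-negative")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    def copy(self) -> "EnvironmentState":
        return EnvironmentState(self.free_counts.copy(), self.volume, self.total_budget)

    def concentrations(self) -> np.ndarray:
        """Molar concentration of every species (vectorized)."""
        return self.free_counts / (AVOGADRO * self.volume)


def init_environment(catalog, total_molecules: int, total_conc: float) -> EnvironmentState:
    """Allocate the molecule budget over the catalog and fix the volume.

    The volume follows from the configured total concentration:
    ``V = total_molecules / (N_A * total_conc)``.  Molecules are split equally
    across the lipid classes present in the catalog, then uniformly across the
    species within each class; integer remainders go to the earliest classes /
    species in catalog order, so the allocation is deterministic and sums to
    ``total_molecules`` exactly.  (With a class knocked out, the same total
    budget is redistributed over the remaining classes.)
    """
    if total_molecules <= 0 or total_conc <= 0:
        raise ValueError("total_molecules and total_conc must be positive")
    volume = total_molecules / (AVOGADRO * total_conc)
    free = np.zeros(len(catalog), dtype=np.int64)
    classes = catalog.classes
    n_classes = len(classes)
    base, extra = divmod(int(total_molecules), n_classes)
    for ci, cls in enumerate(classes):
        class_total = base + (1 if ci < extra else 0)
        members = catalog.class_members(cls)
        sp_base, sp_extra = divmod(class_total, len(members))
        for mi, k in enumerate(members):
            free[k] = sp_base + (1 if mi < sp_extra else 0)
    assert free.sum() == total_molecules
    return EnvironmentState(free, volume, int(total_molecules))


def concentration(env: EnvironmentState, species_index: int) -> float:
    """Molar concentration of one species: ``free_counts[i] / (N_A * V)``."""
    if not 0 <= species_index < len(env.free_counts):
        raise IndexError(f"species index {species_index} out of range")
    return float(env.free_counts[species_index]) / (AVOGADRO * env.volume)


def apply_flux(env: EnvironmentState, delta: np.ndarray) -> EnvironmentState:
    """Apply a net molecule flux to the pool (positive = returned to the pool).

    The caller transfers the negated delta to vesicles, keeping the combined
    total constant.  A flux that would drive any species negative signals a
    stepper bug and raises.
    """
    delta = np.asarray(delta, dtype=np.int64)
    new = env.free_counts + delta
    if (new < 0).any():
        bad = int(np.argmax(new < 0))
        raise ValueError(
            f"flux would drive species {bad} negative "
            f"({env.free_counts[bad]} + {delta[bad]})"
        )
    return EnvironmentState(new, env.volume, env.total_budget)
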