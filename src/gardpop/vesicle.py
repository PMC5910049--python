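"""Vesicle state, composition-derived properties, and division.

A vesicle is an integer composition vector over the catalog species plus
lineage metadata.  Its scalar properties (average chain length, average
unsaturation, mean charge, curvature, CF1, surface area) are pure functionals
of the composition; they feed both the kinetics (rate modification) and the
trajectory analyses.  Division is binomial: on reaching the division threshold
every molecule of the parent is assigned to one of the two progeny with
probability 1/2, independently — the stochastic "assortment" that generates
compositional variability between siblings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Catalog

DIVISION_THRESHOLD = 20_000


@dataclass
class VesicleState:
    vesicle_id: int
    parent_id: int | None
    generation: int
    birth_time: float
    counts: np.ndarray  # non-negative integers over catalog species

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("vesicle counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class VesicleProperties:
    avg_length: float
    avg_unsaturation: float
    charge: float
    curvature: float
    cf1: float
    area: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.avg_length, self.avg_unsaturation, self.charge,
             self.curvature, self.cf1, self.area]
        )


#: column order of property matrices produced by :func:`properties_matrix`
PROPERTY_NAMES = ("avg_length", "avg_unsaturation", "charge", "curvature", "cf1", "area")


def properties_matrix(counts: np.ndarray, catalog: Catalog) -> np.ndarray:
    """Vectorized property computation.

    Parameters
    ----------
    counts : (V, S) integer array, one row per vesicle.

    Returns
    -------
    (V, 6) float array with columns :data:`PROPERTY_NAMES`.  Count-weighted
    means for length/unsaturation/charge/CF1; curvature is the mole-fraction
    weighted sum of per-class curvature coefficients; area is the summed
    head-group area.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("properties are undefined for an empty vesicle")
    frac = counts / totals[:, None]
    out = np.empty((counts.shape[0], 6))
    out[:, 0] = frac @ catalog.lengths
    out[:, 1] = frac @ catalog.unsaturations
    out[:, 2] = frac @ catalog.charges
    out[:, 3] = frac @ catalog.curvature_coefs
    out[:, 4] = frac @ catalog.cf1s
    out[:, 5] = counts @ catalog.head_areas
    return out


def compute_properties(counts: np.ndarray, catalog: Catalog) -> VesicleProperties:
    """Properties of a single composition vector (see :func:`properties_matrix`)."""
    row = properties_matrix(np.asarray(counts), catalog)[0]
    return VesicleProperties(*row)


def divide(
    v: VesicleState,
    rng: np.random.Generator,
    time: float,
    threshold: int = DIVISION_THRESHOLD,
    child_ids: tuple[int, int] | None = None,
) -> tuple[VesicleState, VesicleState]:
    """Split a vesicle at/above the division threshold into two progeny.

    Per species ``i``: ``child1.counts[i] ~ Binomial(v.counts[i], 1/2)`` and
    ``child2.counts[i] = v.counts[i] - child1.counts[i]``, so every molecule is
    conserved exactly.  Both children get ``generation = v.generation + 1``,
    ``parent_id = v.vesicle_id`` and ``birth_time = time``; the parent is
    retired by the caller.

    ``child_ids`` defaults to the collision-free binary-tree scheme
    ``(2*id + 1, 2*id + 2)``; the population stepper supplies sequential ids
    instead.
    """
    if v.total < threshold:
        raise ValueError(
            f"vesicle {v.vesicle_id} has {v.total} lipids, below division "
            f"threshold {threshold}"
        )
    if child_ids is None:
        child_ids = (2 * v.vesicle_id + 1, 2 * v.vesicle_id + 2)
    c1 = rng.binomial(v.counts, 0.5).astype(np.int64)
    c2 = v.counts - c1
    kwargs = dict(parent_id=v.vesicle_id, generation=v.generation + 1, birth_time=time)
    return (
        VesicleState(vesicle_id=child_ids[0], counts=c1, **kwargs),
        VesicleState(vesicle_id=child_ids[1], counts=c2, **kwargs),
    )


def is_shrinking(v_now: VesicleState, v_prev: VesicleState) -> bool:
    """True iff the vesicle's total lipid count strictly decreased between two
    consecutive snapshots of the same vesicle."""
    if v_now.vesicle_id != v_prev.vesicle_id:
        raise ValueError(
            f"snapshot id mismatch: {v_now.vesicle_id} vs {v_prev.vesicle_id}"
        )
    return v_now.total < v_prev.total
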