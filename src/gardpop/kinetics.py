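"""Composition-dependent lipid entry/exit kinetics.

Per vesicle and species the model computes an adjusted entry propensity and an
adjusted per-molecule exit rate:

    kf_adj = k_f * C_i * (A / A_ref)^p * F
    kb_adj = k_b / F

where ``C_i`` is the species' free monomer concentration, ``A`` the vesicle's
surface area (entry scales with the membrane available for insertion) and
``F`` the composition-compatibility factor.  ``F`` couples entry and exit with
one number: lipids compatible with the vesicle's current composition enter
faster *and* leave slower, which is the autocatalytic loop that lets
compositional states propagate.

In *full* mode ``F`` is a product of exponential terms, one per vesicle
property:

    F = exp(-aL |len_i - <len>|) * exp(-aU |u_i - <u>|)
        * exp(-aq q_i Q) * exp(-ac (c_i - K) K) * exp(+af cf1_i CF1)

with ``<len>, <u>, Q, K, CF1`` the vesicle's average length, unsaturation,
mean charge, curvature and CF1, ``c_i`` the species' curvature coefficient and
``q_i`` its charge.  The length/unsaturation terms penalize packing mismatch;
the charge term is like-charge repulsion; the curvature term favors lipids
that relax the vesicle's curvature; the CF1 term is complex formation (SM
self-association, CHOL-SM exclusion).  In *invariant* mode ``F`` is exactly 1
and the rates reduce to mass action.

All factors are clamped to a configurable positive interval so propensities
stay finite for any reachable state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .catalog import Catalog, LipidSpecies
from .vesicle import VesicleProperties

MODES = ("full", "invariant")


@dataclass(frozen=True)
class KineticsConfig:
    mode: str = "full"
    alpha_length: float = 0.1    # per carbon of chain-length mismatch
    alpha_unsat: float = 0.05    # per double bond of mismatch
    alpha_charge: float = 0.5    # like-charge repulsion strength
    alpha_curvature: float = 1.5 # curvature-relaxation strength
    alpha_cf1: float = 2.5       # complex-formation strength
    area_exponent: float = 1.0   # entry ~ (area/area_ref)^p
    factor_floor: float = 1e-6   # clamp bounds for F
    factor_ceiling: float = 1e6

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (0 < self.factor_floor <= 1 <= self.factor_ceiling):
            raise ValueError("factor bounds must bracket 1")

    def as_invariant(self) -> "KineticsConfig":
        """The identical configuration with all modification switched off."""
        return replace(self, mode="invariant")


@dataclass(frozen=True)
class RatePair:
    """Adjusted rates for one species in one vesicle: ``kf_adj`` is the entry
    propensity (events/s per vesicle), ``kb_adj`` the exit rate per molecule."""

    kf_adj: float
    kb_adj: float


def modification_matrix(
    props: np.ndarray,
    catalog: Catalog,
    cfg: KineticsConfig,
) -> np.ndarray:
    """Compatibility factors for every (vesicle, species) pair.

    Parameters
    ----------
    props : (V, 6) array in :data:`gardpop.vesicle.PROPERTY_NAMES` column
        order (as produced by ``properties_matrix``).

    Returns
    -------
    (V, S) strictly positive array; all ones in invariant mode.
    """
    props = np.atleast_2d(np.asarray(props, dtype=float))
    n_v = props.shape[0]
    if cfg.mode == "invariant":
        return np.ones((n_v, len(catalog)))
    avg_len = props[:, 0][:, None]
    avg_u = props[:, 1][:, None]
    q_ves = props[:, 2][:, None]
    curv = props[:, 3][:, None]
    cf1_v = props[:, 4][:, None]
    log_f = (
        -cfg.alpha_length * np.abs(catalog.lengths[None, :] - avg_len)
        - cfg.alpha_unsat * np.abs(catalog.unsaturations[None, :] - avg_u)
        - cfg.alpha_charge * catalog.charges[None, :] * q_ves
        - cfg.alpha_curvature * (catalog.curvature_coefs[None, :] - curv) * curv
        + cfg.alpha_cf1 * catalog.cf1s[None, :] * cf1_v
    )
    return np.clip(np.exp(log_f), cfg.factor_floor, cfg.factor_ceiling)


def modification_factor(
    species: LipidSpecies,
    props: VesicleProperties,
    cfg: KineticsConfig,
    catalog: Catalog | None = None,
) -> float:
    """Scalar compatibility factor for one species entering/leaving one vesicle.

    Exactly the value the vectorized stepper uses (it is computed by the same
    code path on a one-row slice).
    """
    cat = catalog if catalog is not None else Catalog((species,))
    col = cat.index[species.species_id] if catalog is not None else 0
    return float(modification_matrix(props.as_array()[None, :], cat, cfg)[0, col])


def adjusted_rates(
    species: LipidSpecies,
    counts_i: int,
    props: VesicleProperties,
    monomer_conc: float,
    cfg: KineticsConfig,
    area_ref: float,
    catalog: Catalog | None = None,
) -> RatePair:
    """Adjusted entry/exit rates for one species in one vesicle.

    ``kf_adj * dt`` is the expected number of entries of this species into the
    vesicle over a short ``dt``; ``kb_adj * counts_i * dt`` the expected exits.
    """
    if monomer_conc < 0:
        raise ValueError("monomer concentration must be non-negative")
    f = modification_factor(species, props, cfg, catalog)
    area_scale = (props.area / area_ref) ** cfg.area_exponent
    return RatePair(
        kf_adj=species.k_f * monomer_conc * area_scale * f,
        kb_adj=species.k_b / f,
    )
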