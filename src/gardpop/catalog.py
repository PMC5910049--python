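"""Lipid species catalog: the parameter table that defines the simulated chemistry.

The default catalog holds 141 species: four phospholipid classes
(phosphatidylcholine PC, phosphatidylethanolamine PE, phosphatidylserine PS,
sphingomyelin SM) on a grid of 5 acyl-chain lengths x 7 unsaturation levels
(140 species), plus a single cholesterol (CHOL) entry.  Each species carries
the per-molecule constants the kinetics needs: base entry/exit rate constants
``k_f`` (M^-1 s^-1) and ``k_b`` (s^-1), head-group area (m^2), elementary
charge, and the complex-formation index CF1 (CHOL = -1, SM = +3, others 0).

Catalogs are plain data.  They can be written to / read from a CSV file so an
alternative parameter set (e.g. experimentally derived per-species rates) can
be dropped in without touching any simulation code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

CLASS_ORDER: tuple[str, ...] = ("PC", "PE", "PS", "SM", "CHOL")

#: chain-length grid (carbons per acyl chain) for the phospholipid classes
DEFAULT_LENGTHS: tuple[int, ...] = (14, 16, 18, 20, 22)
#: double bonds per chain
DEFAULT_UNSATURATIONS: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)

#: effective chain length assigned to cholesterol (its rigid ring system packs
#: like an 18-carbon chain, which is what makes CHOL-rich vesicles select for
#: lipids of length near 18)
CHOL_EFFECTIVE_LENGTH = 18

# Per-class base rate constants.  Chosen once for the default chemistry and
# shipped as data, constrained by the qualitative ordering the model requires:
# CHOL has the highest k_f, SM the largest k_b, and within PC the saturated
# long-chain species carry the highest k_f (see the length/unsaturation
# modifiers below).  Units: k_f in M^-1 s^-1, k_b in s^-1.
BASE_KF = {"PC": 1.0e11, "PE": 6.25e10, "PS": 6.25e10, "SM": 7.5e10, "CHOL": 4.0e11}
BASE_KB = {"PC": 0.010, "PE": 0.0125, "PS": 0.0125, "SM": 0.025, "CHOL": 0.020}

#: head-group area per molecule, m^2 (order-of-magnitude bilayer values; only
#: relative areas matter for the area property)
HEAD_AREA = {
    "PC": 0.65e-18,
    "PE": 0.55e-18,
    "PS": 0.60e-18,
    "SM": 0.55e-18,
    "CHOL": 0.40e-18,
}

#: per-class curvature coefficients: vesicle curvature is the mole-fraction
#: weighted sum of these, so it tracks CHOL most closely, then SM and PS.
CURVATURE_COEF = {"PC": 0.0, "PE": 0.0, "PS": 0.3, "SM": 0.5, "CHOL": 1.0}

# Within-class k_f modifiers: longer chains insert slightly faster, each double
# bond slows insertion a little.  These make e.g. PC 18:0 one of the
# fastest-entering PC species.
_KF_LENGTH_SLOPE = 0.04  # per carbon away from 18
_KF_UNSAT_FACTOR = 0.97  # per double bond

CSV_FIELDS = (
    "species_id",
    "lipid_class",
    "length",
    "unsaturation",
    "charge",
    "cf1",
    "head_area",
    "k_f",
    "k_b",
)


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog data."""


@dataclass(frozen=True)
class LipidSpecies:
    """Immutable per-species parameter record."""

    species_id: str
    lipid_class: str
    length: int
    unsaturation: int
    charge: int
    cf1: float
    head_area: float
    k_f: float
    k_b: float

    def __post_init__(self) -> None:
        if self.lipid_class not in CLASS_ORDER:
            raise CatalogError(f"unknown lipid class {self.lipid_class!r}")
        if self.k_f <= 0 or self.k_b <= 0:
            raise CatalogError(f"{self.species_id}: rate constants must be positive")
        if self.length <= 0:
            raise CatalogError(f"{self.species_id}: length must be positive")
        if self.unsaturation < 0:
            raise CatalogError(f"{self.species_id}: unsaturation must be >= 0")
        if self.head_area <= 0:
            raise CatalogError(f"{self.species_id}: head_area must be positive")

    @property
    def curvature_coef(self) -> float:
        return CURVATURE_COEF[self.lipid_class]


@dataclass
class Catalog:
    """Ordered collection of :class:`LipidSpecies`.

    The species order is stable and defines the axis of every composition
    vector downstream.  Numpy parameter arrays are cached for the vectorized
    kinetics/property code.
    """

    species: tuple[LipidSpecies, ...]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(f"duplicate species ids: {dupes}")
        if not self.species:
            raise CatalogError("catalog must contain at least one species")
        self.index = {sid: k for k, sid in enumerate(ids)}
        self._build_arrays()

    def _build_arrays(self) -> None:
        sp = self.species
        self.lengths = np.array([s.length for s in sp], dtype=float)
        self.unsaturations = np.array([s.unsaturation for s in sp], dtype=float)
        self.charges = np.array([s.charge for s in sp], dtype=float)
        self.cf1s = np.array([s.cf1 for s in sp], dtype=float)
        self.head_areas = np.array([s.head_area for s in sp], dtype=float)
        self.kf = np.array([s.k_f for s in sp], dtype=float)
        self.kb = np.array([s.k_b for s in sp], dtype=float)
        self.curvature_coefs = np.array([s.curvature_coef for s in sp], dtype=float)
        self.classes = tuple(c for c in CLASS_ORDER if any(s.lipid_class == c for s in sp))
        cls_idx = {c: k for k, c in enumerate(self.classes)}
        self.class_codes = np.array([cls_idx[s.lipid_class] for s in sp], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def __getitem__(self, key: int | str) -> LipidSpecies:
        if isinstance(key, str):
            key = self.index[key]
        return self.species[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return self.species == other.species

    def class_members(self, lipid_class: str) -> list[int]:
        return [k for k, s in enumerate(self.species) if s.lipid_class == lipid_class]

    def class_matrix(self) -> np.ndarray:
        """Boolean (n_classes, n_species) membership matrix in ``self.classes`` order."""
        m = np.zeros((len(self.classes), len(self)), dtype=bool)
        m[self.class_codes, np.arange(len(self))] = True
        return m


def _phospholipid_id(cls: str, length: int, unsat: int) -> str:
    return f"{cls}_{length}:{unsat}"


def generate_default_catalog(
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    unsaturations: Sequence[int] = DEFAULT_UNSATURATIONS,
) -> Catalog:
    """Build the default catalog: 4 classes x len(lengths) x len(unsaturations)
    phospholipids plus one CHOL species (141 species with the default grids).

    Deterministic: two calls return identical catalogs.
    """
    species: list[LipidSpecies] = []
    for cls in ("PC", "PE", "PS", "SM"):
        for length in lengths:
            for unsat in unsaturations:
                kf = (
                    BASE_KF[cls]
                    * (1.0 + _KF_LENGTH_SLOPE * (length - 18))
                    * _KF_UNSAT_FACTOR**unsat
                )
                species.append(
                    LipidSpecies(
                        species_id=_phospholipid_id(cls, length, unsat),
                        lipid_class=cls,
                        length=length,
                        unsaturation=unsat,
                        charge=-1 if cls == "PS" else 0,
                        cf1=3.0 if cls == "SM" else 0.0,
                        head_area=HEAD_AREA[cls],
                        k_f=kf,
                        k_b=BASE_KB[cls],
                    )
                )
    species.append(
        LipidSpecies(
            species_id="CHOL",
            lipid_class="CHOL",
            length=CHOL_EFFECTIVE_LENGTH,
            unsaturation=0,
            charge=0,
            cf1=-1.0,
            head_area=HEAD_AREA["CHOL"],
            k_f=BASE_KF["CHOL"],
            k_b=BASE_KB["CHOL"],
        )
    )
    return Catalog(tuple(species))


def knockout(catalog: Catalog, lipid_class: str) -> Catalog:
    """Return ``catalog`` with every species of ``lipid_class`` removed."""
    if lipid_class not in {s.lipid_class for s in catalog}:
        raise CatalogError(f"class {lipid_class!r} not present in catalog")
    return Catalog(tuple(s for s in catalog if s.lipid_class != lipid_class))


def single_lipid_catalog(species_id: str, base: Catalog | None = None) -> Catalog:
    """One-species catalog for homogeneous-vesicle runs (e.g. ``PC_16:0`` as a
    DPPC analogue or ``PC_18:1`` as a DOPC analogue)."""
    base = base if base is not None else generate_default_catalog()
    if species_id not in base.index:
        raise CatalogError(f"unknown species id {species_id!r}")
    return Catalog((base[species_id],))


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog as a UTF-8 CSV with one row per species."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_FIELDS)
        for s in catalog:
            writer.writerow(
                [
                    s.species_id,
                    s.lipid_class,
                    s.length,
                    s.unsaturation,
                    s.charge,
                    repr(s.cf1),
                    repr(s.head_area),
                    repr(s.k_f),
                    repr(s.k_b),
                ]
            )


def load_catalog(path: str | Path) -> Catalog:
    """Load a catalog CSV written by :func:`write_catalog` (or by hand).

    The header must contain exactly the :data:`CSV_FIELDS` columns; row order
    is preserved and defines the composition-vector axis.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != set(CSV_FIELDS):
            missing = set(CSV_FIELDS) - set(reader.fieldnames or [])
            raise CatalogError(f"catalog file {path}: missing columns {sorted(missing)}")
        species = []
        for row in reader:
            try:
                species.append(
                    LipidSpecies(
                        species_id=row["species_id"],
                        lipid_class=row["lipid_class"],
                        length=int(row["length"]),
                        unsaturation=int(row["unsaturation"]),
                        charge=int(row["charge"]),
                        cf1=float(row["cf1"]),
                        head_area=float(row["head_area"]),
                        k_f=float(row["k_f"]),
                        k_b=float(row["k_b"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, CatalogError):
                    raise
                raise CatalogError(f"catalog file {path}: bad row {row!r}: {exc}") from exc
    return Catalog(tuple(species))


def make_toy_catalog(
    n_per_class: int = 2,
    classes: Iterable[str] = CLASS_ORDER,
) -> Catalog:
    """Small deterministic catalog for tests and quick runs.

    Takes the first ``n_per_class`` species of each requested class from the
    default enumeration (CHOL contributes its single species).
    """
    default = generate_default_catalog()
    species: list[LipidSpecies] = []
    for cls in classes:
        members = default.class_members(cls)[:n_per_class]
        species.extend(default.species[k] for k in members)
    return Catalog(tuple(species))
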