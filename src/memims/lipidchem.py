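"""Lipid species construction and adduct-mass assignment.

Lipids are modelled at the level the experiments resolve them: a lipid
class (PE, PG, CDL, MAG) plus a total acyl composition ``n:d`` (total
acyl-chain carbons : total double bonds summed over all chains).  The
distribution of carbons among individual chains is not modelled.

Molecular formulas are built from the class's zero-acyl free-acid
backbone (all acyl positions as free hydroxyls) plus the acyl
composition: esterifying a fatty acid with ``c`` carbons and ``u``
double bonds adds ``C_c H_{2c-2-2u} O``.

Cardiolipin is reported by default in its singly deprotonated form
(one acidic phosphate ionized), which is how its mass is conventionally
printed in bacterial lipidomics; all other classes default to the
neutral free acid.  Both forms are available for every class via the
``form`` argument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LipidClass",
    "LipidSpecies",
    "AdductAssignment",
    "build_species",
    "assign_adduct",
    "series_spacing",
]

# IUPAC standard atomic weights and principal-isotope masses (Da).
ATOMIC_WEIGHTS = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
}
MONOISOTOPIC_MASSES = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}


class LipidClass(str, Enum):
    """Lipid classes resolvable from adduct masses in native MS."""

    PE = "PE"
    PG = "PG"
    CDL = "CDL"
    MAG = "MAG"


# Zero-acyl backbone formulas (free acid, all acyl positions -OH) and the
# number of acyl chains each class carries.
#   PE : glycerophosphoethanolamine  C5H14NO6P
#   PG : glycerophosphoglycerol      C6H15O8P
#   CDL: bis(glycerophospho)glycerol C9H22O13P2
#   MAG: glycerol                    C3H8O3
_BACKBONES: dict[LipidClass, tuple[dict[str, int], int]] = {
    LipidClass.PE: ({"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}, 2),
    LipidClass.PG: ({"C": 6, "H": 15, "O": 8, "P": 1}, 2),
    LipidClass.CDL: ({"C": 9, "H": 22, "O": 13, "P": 2}, 4),
    LipidClass.MAG: ({"C": 3, "H": 8, "O": 3}, 1),
}

# Classes whose reported masses follow the [M-H] convention by default.
_DEFAULT_ANIONIC = frozenset({LipidClass.CDL})

#: Documented assignment tolerance absorbing protonation/salt-form ambiguity.
ASSIGNMENT_TOLERANCE_DA = 0.5


def n_chains(lipid_class: LipidClass) -> int:
    """Number of acyl chains carried by a lipid class (CDL 4, PE/PG 2, MAG 1)."""
    return _BACKBONES[LipidClass(lipid_class)][1]


def _formula_mass(formula: dict[str, int], table: dict[str, float]) -> float:
    return sum(table[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class with total acyl composition and derived masses."""

    lipid_class: LipidClass
    n_carbons: int
    n_double_bonds: int
    molecular_formula: dict[str, int] = field(compare=False)
    average_mass: float = field(compare=False)
    monoisotopic_mass: float = field(compare=False)
    form: str = field(default="free_acid", compare=True)

    @property
    def composition(self) -> str:
        return f"{self.n_carbons}:{self.n_double_bonds}"

    @property
    def name(self) -> str:
        return f"{self.lipid_class.value} {self.composition}"

    def to_dict(self) -> dict:
        return {
            "lipid_class": self.lipid_class.value,
            "n_carbons": self.n_carbons,
            "n_double_bonds": self.n_double_bonds,
            "molecular_formula": dict(self.molecular_formula),
            "average_mass": self.average_mass,
            "monoisotopic_mass": self.monoisotopic_mass,
            "form": self.form,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_species(
    lipid_class: LipidClass | str,
    n_carbons: int,
    n_double_bonds: int,
    form: str = "auto",
) -> LipidSpecies:
    """Construct a lipid species from class and total acyl composition.

    Parameters
    ----------
    lipid_class
        One of ``PE``, ``PG``, ``CDL``, ``MAG``.
    n_carbons
        Total acyl-chain carbons (summed over all chains).
    n_double_bonds
        Total acyl-chain double bonds.
    form
        ``"free_acid"`` for the neutral species, ``"anion"`` for the singly
        deprotonated [M-H] form, or ``"auto"`` (default) for the class
        convention: [M-H] for CDL, free acid otherwise.

    Returns
    -------
    LipidSpecies
        With molecular formula and average/monoisotopic masses.
    """
    try:
        cls = LipidClass(lipid_class)
    except ValueError as exc:
        raise ValueError(f"unknown lipid class: {lipid_class!r}") from exc
    backbone, chains = _BACKBONES[cls]
    if n_double_bonds < 0:
        raise ValueError("n_double_bonds must be non-negative")
    if n_carbons < 2 * chains:
        raise ValueError(
            f"{cls.value} carries {chains} acyl chains; "
            f"n_carbons must be >= {2 * chains} (got {n_carbons})"
        )
    if form == "auto":
        form = "anion" if cls in _DEFAULT_ANIONIC else "free_acid"
    if form not in ("free_acid", "anion"):
        raise ValueError(f"unknown form: {form!r}")

    formula = dict(backbone)
    formula["C"] = formula.get("C", 0) + n_carbons
    # Each acyl chain contributes 2c-2-2u hydrogens and one ester oxygen.
    formula["H"] = formula.get("H", 0) + 2 * n_carbons - 2 * chains - 2 * n_double_bonds
    formula["O"] = formula.get("O", 0) + chains
    if form == "anion":
        formula["H"] -= 1
    if formula["H"] < 0:
        raise ValueError(
            f"composition {n_carbons}:{n_double_bonds} is over-unsaturated "
            f"for {cls.value}"
        )
    return LipidSpecies(
        lipid_class=cls,
        n_carbons=n_carbons,
        n_double_bonds=n_double_bonds,
        molecular_formula=formula,
        average_mass=_formula_mass(formula, ATOMIC_WEIGHTS),
        monoisotopic_mass=_formula_mass(formula, MONOISOTOPIC_MASSES),
        form=form,
    )


@dataclass(frozen=True)
class AdductAssignment:
    """Best-matching lipid composition for an observed adduct mass."""

    observed_mass: float
    best_species: LipidSpecies
    mass_error: float
    candidate_ranking: tuple[tuple[LipidSpecies, float], ...]

    def to_dict(self) -> dict:
        return {
            "observed_mass": self.observed_mass,
            "best_species": self.best_species.to_dict(),
            "mass_error": self.mass_error,
            "candidate_ranking": [
                {"species": s.name, "abs_error": e}
                for s, e in self.candidate_ranking
            ],
        }


def assign_adduct(
    observed_mass: float,
    lipid_class: LipidClass | str,
    carbon_range: tuple[int, int] = (60, 80),
    double_bond_range: tuple[int, int] = (0, 8),
    form: str = "auto",
    max_candidates: int | None = None,
) -> AdductAssignment:
    """Assign an observed adduct mass to the closest acyl composition.

    Every composition in the inclusive search range is scored by
    ``|average_mass - observed_mass|``; ties are broken by fewer double
    bonds, then fewer carbons.
    """
    if observed_mass <= 0:
        raise ValueError("observed_mass must be positive")
    cls = LipidClass(lipid_class)
    n_lo, n_hi = carbon_range
    d_lo, d_hi = double_bond_range
    candidates: list[tuple[float, int, int, LipidSpecies]] = []
    for n in range(n_lo, n_hi + 1):
        for d in range(d_lo, d_hi + 1):
            try:
                sp = build_species(cls, n, d, form=form)
            except ValueError:
                continue
            candidates.append((abs(sp.average_mass - observed_mass), d, n, sp))
    if not candidates:
        raise ValueError(
            f"empty candidate set for {cls.value} in range "
            f"{n_lo}:{d_lo}..{n_hi}:{d_hi}"
        )
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    if max_candidates is not None:
        ranked = candidates[:max_candidates]
    else:
        ranked = candidates
    best = ranked[0][3]
    return AdductAssignment(
        observed_mass=observed_mass,
        best_species=best,
        mass_error=best.average_mass - observed_mass,
        candidate_ranking=tuple((sp, err) for err, _, _, sp in ranked),
    )


def series_spacing(masses: Sequence[float] | Iterable[float]) -> float:
    """Robust (median) spacing between consecutive sorted masses.

    Used to recognize homologous adduct series: consecutive acyl-chain
    lengths at fixed unsaturation are spaced by one two-carbon increment
    (28.05 Da, printed as 28 Da).
    """
    arr = np.sort(np.asarray(list(masses), dtype=float))
    if arr.size < 2:
        raise ValueError("need at least 2 masses to estimate a spacing")
    return float(np.median(np.diff(arr)))
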