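"""Combinatorial in-silico library of acidic glycosphingolipids.

Gangliosides and sulfatides are built from a ceramide (sphingoid base +
fatty acyl, described by a sum composition such as ``d36:1``) carrying an
oligosaccharide headgroup assembled from dehydrated monosaccharide residues
(Hex, HexNAc, NeuAc) and additive modifications (O-acetyl, sulfate).  The
module enumerates species over a configurable ceramide grid, computes exact
monoisotopic masses and elemental formulas by two independent routes
(residue-mass summation and atom-count summation), and derives theoretical
m/z values for multiply deprotonated negative-mode ions.

Class names follow Svennerholm nomenclature: the letter after ``G`` encodes
the sialic-acid count (M=1, D=2, T=3, Q=4); the trailing letter (a/b/c)
distinguishes linkage isomers, which are mass-identical and tracked here
only through ``isomer_label``.  O-acetylated variants append ``-Ac`` /
``-Ac2``; ``ST`` is sulfatide and ``dihexST`` the dihexosylated sulfatide.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "Monomer",
    "MONOMERS",
    "CeramideComposition",
    "GlycanHeadgroup",
    "GLYCAN_CLASSES",
    "LipidSpecies",
    "IonSpecies",
    "ShorthandError",
    "formula_mass",
    "hill_formula",
    "residue_mass",
    "ceramide_mass",
    "species_mass",
    "make_species",
    "ion_mz",
    "headgroup",
    "default_charge_states",
    "enumerate_species",
    "enumerate_library",
    "find_anchor_species",
    "library_table",
    "parse_shorthand",
]

# Monoisotopic atomic masses (Da).
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
}

PROTON_MASS = 1.00727646

Formula = Mapping[str, int]


def formula_mass(formula: Formula) -> float:
    """Monoisotopic mass of an elemental composition.

    Raises ``ValueError`` for elements outside the supported CHNOS set.
    """
    mass = 0.0
    for element, count in formula.items():
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula")
        mass += ATOMIC_MASS[element] * count
    return mass


def formula_add(*formulas: Formula) -> dict[str, int]:
    out: dict[str, int] = {}
    for f in formulas:
        for element, count in f.items():
            out[element] = out.get(element, 0) + count
    return {e: c for e, c in out.items() if c != 0}


def formula_scale(formula: Formula, k: int) -> dict[str, int]:
    return {e: c * k for e, c in formula.items() if c != 0}


def hill_formula(formula: Formula) -> str:
    """Hill-notation string: C first, H second, then alphabetical."""
    parts = []
    rest = sorted(e for e in formula if e not in ("C", "H"))
    for element in [e for e in ("C", "H") if e in formula] + rest:
        count = formula[element]
        if count == 0:
            continue
        parts.append(element if count == 1 else f"{element}{count}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Monomer:
    """A dehydrated saccharide residue or additive modification."""

    name: str
    formula: Mapping[str, int]

    @property
    def residue_mass(self) -> float:
        return formula_mass(self.formula)


MONOMERS: dict[str, Monomer] = {
    "Hex": Monomer("Hex", {"C": 6, "H": 10, "O": 5}),
    "HexNAc": Monomer("HexNAc", {"C": 8, "H": 13, "N": 1, "O": 5}),
    "NeuAc": Monomer("NeuAc", {"C": 11, "H": 17, "N": 1, "O": 8}),
    "OAc": Monomer("OAc", {"C": 2, "H": 2, "O": 1}),
    "SO3": Monomer("SO3", {"S": 1, "O": 3}),
}


def residue_mass(name: str) -> float:
    """Monoisotopic residue mass of a registered building block."""
    try:
        return MONOMERS[name].residue_mass
    except KeyError:
        raise ValueError(f"unknown monomer {name!r}; known: {sorted(MONOMERS)}") from None


@dataclass(frozen=True, order=True)
class CeramideComposition:
    """Ceramide sum composition: base type, total carbons, total double bonds.

    ``d`` denotes a dihydroxy sphingoid base (formula C(n)H(2n+1-2db)NO3),
    ``t`` a trihydroxy base (one extra oxygen).
    """

    base_type: str
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.base_type not in ("d", "t"):
            raise ValueError(f"base_type must be 'd' or 't', got {self.base_type!r}")
        if self.carbons < 1:
            raise ValueError(f"carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double_bonds must be >= 0, got {self.double_bonds}")
        if 2 * self.carbons + 1 - 2 * self.double_bonds <= 0:
            raise ValueError(
                f"double bond count {self.double_bonds} too large for "
                f"{self.carbons} carbons (negative hydrogen count)"
            )

    @property
    def formula(self) -> dict[str, int]:
        n, db = self.carbons, self.double_bonds
        oxygens = 3 if self.base_type == "d" else 4
        return {"C": n, "H": 2 * n + 1 - 2 * db, "N": 1, "O": oxygens}

    @property
    def mass(self) -> float:
        return formula_mass(self.formula)

    def __str__(self) -> str:
        return f"{self.base_type}{self.carbons}:{self.double_bonds}"


def ceramide_mass(cer: CeramideComposition) -> tuple[float, dict[str, int]]:
    """Neutral monoisotopic mass and elemental formula of a ceramide."""
    return cer.mass, cer.formula


@dataclass(frozen=True)
class GlycanHeadgroup:
    """A glycan headgroup composition with a class name and isomer label."""

    class_name: str
    counts: Mapping[str, int]
    isomer_label: str = ""

    def __post_init__(self) -> None:
        for name in self.counts:
            if name not in MONOMERS:
                raise ValueError(f"unknown monomer {name!r} in headgroup {self.class_name}")

    @property
    def residue_mass_sum(self) -> float:
        return sum(MONOMERS[m].residue_mass * k for m, k in self.counts.items())

    @property
    def formula(self) -> dict[str, int]:
        return formula_add(*(formula_scale(MONOMERS[m].formula, k) for m, k in self.counts.items()))

    @property
    def n_sialic(self) -> int:
        return self.counts.get("NeuAc", 0)


def _gs(hexose: int, hexnac: int, neuac: int, oac: int = 0) -> dict[str, int]:
    counts = {"Hex": hexose, "HexNAc": hexnac, "NeuAc": neuac, "OAc": oac}
    return {k: v for k, v in counts.items() if v > 0}


#: Default class list: the gangliotetraose-series gangliosides, their
#: O-acetylated variants, and the sulfatides.  Configuration-driven callers
#: can pass any subset or additional compositions to the enumerators.
GLYCAN_CLASSES: dict[str, dict[str, int]] = {
    "GM3": _gs(2, 0, 1),
    "GM2": _gs(2, 1, 1),
    "GM1a": _gs(3, 1, 1),
    "GM1b": _gs(3, 1, 1),
    "GD3": _gs(2, 0, 2),
    "GD2": _gs(2, 1, 2),
    "GD1a": _gs(3, 1, 2),
    "GD1b": _gs(3, 1, 2),
    "GT3": _gs(2, 0, 3),
    "GT2": _gs(2, 1, 3),
    "GT1a": _gs(3, 1, 3),
    "GT1b": _gs(3, 1, 3),
    "GT1c": _gs(3, 1, 3),
    "GQ1b": _gs(3, 1, 4),
    "GQ1c": _gs(3, 1, 4),
    "GD1-Ac": _gs(3, 1, 2, oac=1),
    "GT1b-Ac": _gs(3, 1, 3, oac=1),
    "GQ1b-Ac": _gs(3, 1, 4, oac=1),
    "GT1b-Ac2": _gs(3, 1, 3, oac=2),
    "GQ1b-Ac2": _gs(3, 1, 4, oac=2),
    "ST": {"Hex": 1, "SO3": 1},
    "dihexST": {"Hex": 2, "SO3": 1},
}

_ISOMER_RE = re.compile(r"^G[MDTQ]\d([abc])")


def headgroup(class_name: str) -> GlycanHeadgroup:
    """Look up a registered glycan class by (case-sensitive) name."""
    try:
        counts = GLYCAN_CLASSES[class_name]
    except KeyError:
        raise ValueError(f"unknown glycan class {class_name!r}") from None
    m = _ISOMER_RE.match(class_name)
    return GlycanHeadgroup(class_name, counts, isomer_label=m.group(1) if m else "")


# ---------------------------------------------------------------------------
# Species and ions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSpecies:
    """A glycan headgroup attached to a ceramide sum composition."""

    headgroup: GlycanHeadgroup
    ceramide: CeramideComposition

    @property
    def shorthand(self) -> str:
        return f"{self.headgroup.class_name} {self.ceramide}"

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic mass by residue-mass summation."""
        return self.ceramide.mass + self.headgroup.residue_mass_sum

    @property
    def formula(self) -> dict[str, int]:
        return formula_add(self.ceramide.formula, self.headgroup.formula)

    @property
    def mass_from_formula(self) -> float:
        """Monoisotopic mass recomputed from the assembled elemental formula."""
        return formula_mass(self.formula)

    def __str__(self) -> str:
        return self.shorthand


def make_species(class_name: str, base_type: str, carbons: int, double_bonds: int) -> LipidSpecies:
    return LipidSpecies(headgroup(class_name), CeramideComposition(base_type, carbons, double_bonds))


def species_mass(species: LipidSpecies) -> tuple[float, dict[str, int]]:
    """Neutral monoisotopic mass and full elemental formula of a species."""
    return species.neutral_mass, species.formula


def ion_mz(species: LipidSpecies, charge: int) -> float:
    """Theoretical m/z of the ``charge``-fold deprotonated anion [M-zH]z-."""
    if charge <= 0:
        raise ValueError(f"charge must be a positive deprotonation count, got {charge}")
    return (species.neutral_mass - charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class IonSpecies:
    """A deprotonated charge state of a lipid species."""

    species: LipidSpecies
    charge: int

    @property
    def theo_mz(self) -> float:
        return ion_mz(self.species, self.charge)


def default_charge_states(hg: GlycanHeadgroup) -> tuple[int, ...]:
    """Negative-mode charge states observed per class on HILIC-ESI.

    Mono/asialo species and sulfatides appear at 1- and 2-; di-sialylated
    species predominantly at 2-; tri- and higher sialylated species at 2-
    and 3-.
    """
    n = hg.n_sialic
    if n <= 1:
        return (1, 2)
    if n == 2:
        return (2,)
    return (2, 3)


def enumerate_species(
    classes: Sequence[str] | None = None,
    carbons: Iterable[int] = range(28, 49),
    double_bonds: Iterable[int] = range(0, 5),
    base_types: Sequence[str] = ("d", "t"),
) -> list[LipidSpecies]:
    """Enumerate the species grid, sorted by (class, base, carbons, db)."""
    if classes is None:
        classes = list(GLYCAN_CLASSES)
    if not classes:
        raise ValueError("class list must be non-empty")
    out = []
    seen = set()
    for cls in sorted(classes):
        hg = headgroup(cls)
        for base, c, db in itertools.product(sorted(base_types), sorted(carbons), sorted(double_bonds)):
            key = (cls, base, c, db)
            if key in seen:
                continue
            seen.add(key)
            out.append(LipidSpecies(hg, CeramideComposition(base, c, db)))
    return out


def enumerate_library(
    classes: Sequence[str] | None = None,
    carbons: Iterable[int] = range(28, 49),
    double_bonds: Iterable[int] = range(0, 5),
    base_types: Sequence[str] = ("d", "t"),
    charge_states: Mapping[str, Sequence[int]] | None = None,
    mz_range: tuple[float, float] | None = (300.0, 2000.0),
) -> list[IonSpecies]:
    """Enumerate library ions over the species grid.

    ``charge_states`` maps class name to the deprotonation counts to emit;
    classes not listed fall back to :func:`default_charge_states`.  Ions
    outside ``mz_range`` (the acquired mass range) are clipped; pass
    ``None`` to disable clipping.  The result is duplicate-free and sorted
    by (class, base type, carbons, double bonds, charge).
    """
    ions = []
    for sp in enumerate_species(classes, carbons, double_bonds, base_types):
        if charge_states is not None and sp.headgroup.class_name in charge_states:
            zs = charge_states[sp.headgroup.class_name]
        else:
            zs = default_charge_states(sp.headgroup)
        for z in sorted(zs):
            ion = IonSpecies(sp, z)
            if mz_range is not None and not (mz_range[0] <= ion.theo_mz <= mz_range[1]):
                continue
            ions.append(ion)
    return ions


def library_table(ions: Sequence[IonSpecies]) -> pd.DataFrame:
    """Flat export of library ions (one row per charge state)."""
    rows = []
    for ion in ions:
        sp = ion.species
        rows.append(
            {
                "class": sp.headgroup.class_name,
                "isomer_label": sp.headgroup.isomer_label,
                "base_type": sp.ceramide.base_type,
                "carbons": sp.ceramide.carbons,
                "db": sp.ceramide.double_bonds,
                "shorthand": sp.shorthand,
                "formula": hill_formula(sp.formula),
                "neutral_mass": sp.neutral_mass,
                "charge": ion.charge,
                "theo_mz": ion.theo_mz,
            }
        )
    return pd.DataFrame(rows)


def find_anchor_species(
    class_name: str,
    printed_mz: float,
    charge: int,
    tol_th: float = 0.1,
    carbons: Iterable[int] = range(28, 49),
    double_bonds: Iterable[int] = range(0, 5),
    base_types: Sequence[str] = ("d",),
) -> list[IonSpecies]:
    """Exhaustively search a class's ceramide grid for ions matching a
    printed (rounded) m/z value within ``tol_th`` Thomson.

    Used to recover the ceramide composition behind a figure-caption m/z.
    Gangliosides are searched over the d-series by default: brain
    ganglioside ceramides carry dihydroxy sphingoid bases, while the
    t-series part of the default enumeration grid serves the sulfatides
    (e.g. ST t36:1).  Matches are sorted by absolute m/z error.
    """
    hits = [
        ion
        for ion in enumerate_library(
            classes=[class_name],
            carbons=carbons,
            double_bonds=double_bonds,
            base_types=base_types,
            charge_states={class_name: [charge]},
            mz_range=None,
        )
        if abs(ion.theo_mz - printed_mz) <= tol_th
    ]
    hits.sort(key=lambda ion: abs(ion.theo_mz - printed_mz))
    return hits


class ShorthandError(ValueError):
    """Raised when a lipid shorthand string cannot be parsed."""


_SHORTHAND_RE = re.compile(r"^(?P<cls>\S+)\s+(?P<base>[dt])(?P<carbons>\d+):(?P<db>\d+)$")


def parse_shorthand(text: str) -> LipidSpecies:
    """Parse ``"<class> <d|t><carbons>:<double bonds>"`` (e.g. ``"GM1a d42:2"``).

    Round-trips with :attr:`LipidSpecies.shorthand`; class names are
    case-sensitive.
    """
    m = _SHORTHAND_RE.match(text.strip())
    if m is None:
        raise ShorthandError(f"cannot parse lipid shorthand {text!r}")
    cls = m.group("cls")
    if cls not in GLYCAN_CLASSES:
        raise ShorthandError(f"unknown glycan class {cls!r} in shorthand {text!r}")
    return make_species(cls, m.group("base"), int(m.group("carbons")), int(m.group("db")))
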