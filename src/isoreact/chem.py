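"""Element and isotope bookkeeping, formula arithmetic, and molecular indices.

Masses are monoisotopic and exact; what "monoisotopic" means is controlled by
the active :class:`IsotopeTable`.  For an isotopically enriched experiment
(e.g. a ¹⁵N-labeled chloramination study) the table is *relabeled* so that the
enriched isotope becomes the principal isotope of its element — from then on
every formula mass, every predicted isotopologue and every m/z in the pipeline
is computed in the enriched frame, and the symbol "N" denotes the labeled
nitrogen throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Isotope",
    "IsotopeTable",
    "MolecularFormula",
    "ElementLimits",
    "Transformation",
    "load_isotope_table",
    "default_isotope_table",
    "nitrogen15_table",
    "parse_formula",
    "format_formula",
    "apply_transformation",
    "monoisotopic_mass",
    "mz_deprotonated",
    "neutral_from_mz",
    "ppm_error",
    "double_bond_equivalent",
    "aromaticity_index",
    "relabel_isotope",
]

#: Mass of the proton in Da.  A deprotonated [M-H]⁻ ion at charge 1 has
#: m/z = M - PROTON_MASS (equivalently M - m(¹H) + m(e⁻)).
PROTON_MASS = 1.00727646

#: Mass of the electron in Da.
ELECTRON_MASS = 0.00054858

# Elements with defined valence conventions for DBE / aromaticity index.
# C tetravalent, H/F/Cl monovalent, N trivalent, O/S divalent.
_DBE_ELEMENTS = frozenset({"C", "H", "O", "N", "F", "Cl", "S"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Isotope:
    """A single isotope of an element."""

    label: str
    mass: float  # Da
    abundance: float  # fraction in [0, 1]


class IsotopeTable:
    """Per-element isotope masses and abundances.

    The first-listed isotope of each element is the *principal* isotope: the
    one that defines the monoisotopic mass.  Relabeling (see
    :func:`relabel_isotope`) reorders and re-weights the isotopes of one
    element to reflect isotopic enrichment.
    """

    proton_mass = PROTON_MASS
    electron_mass = ELECTRON_MASS

    def __init__(self, elements: Mapping[str, tuple[Isotope, ...]]):
        self._elements = {el: tuple(isos) for el, isos in elements.items()}
        self._validate()

    def _validate(self) -> None:
        for el, isos in self._elements.items():
            if not isos:
                raise ValueError(f"element {el!r} has no isotopes")
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances of {el!r} sum to {total!r}, expected 1"
                )
            if any(i.mass <= 0 for i in isos):
                raise ValueError(f"element {el!r} has a non-positive isotope mass")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._elements)

    def __contains__(self, element: str) -> bool:
        return element in self._elements

    def isotopes(self, element: str) -> tuple[Isotope, ...]:
        try:
            return self._elements[element]
        except KeyError:
            raise KeyError(f"element {element!r} not in isotope table") from None

    def principal(self, element: str) -> Isotope:
        """The isotope defining the monoisotopic mass of *element*."""
        return self.isotopes(element)[0]

    def principal_mass(self, element: str) -> float:
        return self.principal(element).mass

    def minor(self, element: str) -> Isotope | None:
        """Most abundant non-principal isotope, or None for mono-isotopic elements."""
        others = self.isotopes(element)[1:]
        if not others:
            return None
        best = max(others, key=lambda i: i.abundance)
        return best if best.abundance > 0 else None

    def as_mapping(self) -> dict[str, tuple[Isotope, ...]]:
        return dict(self._elements)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["element", "isotope", "mass", "abundance"])
            for el, isos in self._elements.items():
                for iso in isos:
                    w.writerow([el, iso.label, repr(iso.mass), repr(iso.abundance)])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(
            f"{el}:{self.principal(el).label}" for el in self._elements
        )
        return f"IsotopeTable({parts})"


def load_isotope_table(path=None) -> IsotopeTable:
    """Load an isotope table from a CSV of (element, isotope, mass, abundance) rows.

    Row order matters: the first row of each element is the principal isotope.
    With no *path*, the bundled natural-abundance table (C, H, O, N, F, Cl, S)
    is loaded.
    """
    if path is None:
        ref = resources.files("isoreact.data").joinpath("isotopes.csv")
        text = ref.read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    elements: dict[str, list[Isotope]] = {}
    for row in rows:
        elements.setdefault(row["element"], []).append(
            Isotope(row["isotope"], float(row["mass"]), float(row["abundance"]))
        )
    return IsotopeTable({el: tuple(isos) for el, isos in elements.items()})


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """The bundled natural-abundance isotope table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_isotope_table()
    return _DEFAULT_TABLE


def nitrogen15_table(enrichment: float = 0.982) -> IsotopeTable:
    """Isotope table for a ¹⁵N-enriched experiment.

    ¹⁵N becomes the principal nitrogen isotope at the stated enrichment
    (default 98.2%, the enrichment of commercial ¹⁵NH₄Cl); the residual
    abundance goes to ¹⁴N, which then appears only as a minor isotopologue.
    """
    return relabel_isotope(default_isotope_table(), "N", "15N", enrichment)


def relabel_isotope(
    table: IsotopeTable, element: str, principal_isotope: str, enrichment: float
) -> IsotopeTable:
    """Make *principal_isotope* the principal isotope of *element*.

    The chosen isotope is moved first with abundance equal to *enrichment*;
    the remaining 1 - enrichment is distributed over the other isotopes in
    proportion to their current abundances.
    """
    if not 0.0 < enrichment <= 1.0:
        raise ValueError(f"enrichment must be in (0, 1], got {enrichment}")
    isos = table.isotopes(element)
    chosen = [i for i in isos if i.label == principal_isotope]
    if not chosen:
        raise KeyError(f"isotope {principal_isotope!r} not found for {element!r}")
    target = chosen[0]
    others = [i for i in isos if i.label != principal_isotope]
    rest = sum(i.abundance for i in others)
    new: list[Isotope] = [Isotope(target.label, target.mass, enrichment)]
    for iso in others:
        frac = iso.abundance / rest if rest > 0 else 1.0 / len(others)
        new.append(Isotope(iso.label, iso.mass, (1.0 - enrichment) * frac))
    elements = table.as_mapping()
    elements[element] = tuple(new)
    return IsotopeTable(elements)


class MolecularFormula(Mapping):
    """An elemental composition: element symbol → non-negative count.

    Immutable, hashable, and comparable element-wise.  Zero counts are
    dropped, so ``MolecularFormula({"C": 1, "N": 0}) == MolecularFormula({"C": 1})``.
    Supports ``+`` (element-wise sum); subtraction is expressed through
    :class:`Transformation` deltas, which may be signed.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None):
        cleaned: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if not isinstance(n, int):
                raise TypeError(f"count for {el!r} must be int, got {type(n).__name__}")
            if n < 0:
                raise ValueError(f"negative count for {el!r}: {n}")
            if n > 0:
                cleaned[el] = n
        object.__setattr__(self, "_counts", dict(sorted(cleaned.items())))
        object.__setattr__(self, "_hash", hash(tuple(self._counts.items())))

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("MolecularFormula is immutable")

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element) -> bool:
        return element in self._counts

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        return NotImplemented

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"MolecularFormula({format_formula(self)!r})"


def parse_formula(text: str, known_elements=None) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C6H4Cl3NO4"``.

    An omitted count means 1.  Element symbols are validated against
    *known_elements* (default: elements of the bundled isotope table).
    """
    if known_elements is None:
        known_elements = default_isotope_table().elements
    if not isinstance(text, str) or not text:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in known_elements:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def format_formula(f: MolecularFormula) -> str:
    """Format a formula in Hill notation: C, H, then other elements alphabetically."""
    if not f:
        return ""
    parts: list[str] = []
    order = [el for el in ("C", "H") if el in f]
    order += sorted(el for el in f if el not in ("C", "H"))
    for el in order:
        n = f[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


#: element symbol → maximum allowed count
ElementLimits = dict


@dataclass(frozen=True)
class Transformation:
    """A named reaction type expressed as a signed elemental change.

    ``delta`` maps element → signed count change, reactant → product.
    Example: chlorination (H → Cl) is ``{"H": -1, "Cl": +1}``.
    """

    name: str
    delta: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.delta.items() if n != 0}
        if not clean:
            raise ValueError(f"transformation {self.name!r} has an empty delta")
        object.__setattr__(self, "delta", clean)

    def mass_delta(self, table: IsotopeTable) -> float:
        return sum(n * table.principal_mass(el) for el, n in self.delta.items())


class TransformationNotApplicable(ValueError):
    """Applying the transformation would drive an element count negative."""


def apply_transformation(f: MolecularFormula, t: Transformation) -> MolecularFormula:
    """Apply the elemental change of *t* to *f* (reactant → product)."""
    counts = dict(f)
    for el, dn in t.delta.items():
        new = counts.get(el, 0) + dn
        if new < 0:
            raise TransformationNotApplicable(
                f"{t.name} not applicable to {format_formula(f)}: "
                f"{el} count would be {new}"
            )
        counts[el] = new
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula, table: IsotopeTable | None = None) -> float:
    """Monoisotopic neutral mass in Da under the table's principal isotopes."""
    if table is None:
        table = default_isotope_table()
    return sum(n * table.principal_mass(el) for el, n in f.items())


def mz_deprotonated(neutral_mass: float) -> float:
    """m/z of the [M-H]⁻ ion at charge 1."""
    if neutral_mass <= PROTON_MASS:
        raise ValueError(f"neutral mass {neutral_mass} not above the proton mass")
    return neutral_mass - PROTON_MASS


def neutral_from_mz(mz: float) -> float:
    """Neutral monoisotopic mass recovered from a deprotonated m/z (charge 1)."""
    if mz <= 0:
        raise ValueError(f"non-positive m/z {mz}")
    return mz + PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"non-positive theoretical m/z {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def _check_dbe_elements(f: MolecularFormula) -> None:
    bad = set(f) - _DBE_ELEMENTS
    if bad:
        raise ValueError(f"unsupported element(s) for valence indices: {sorted(bad)}")


def double_bond_equivalent(f: MolecularFormula) -> float:
    """Rings-plus-π-bonds count: DBE = 1 + C - (H + F + Cl)/2 + N/2.

    Halogens count as hydrogens, N is trivalent, O and S contribute nothing.
    May be half-integer; an even-electron neutral molecule has integer DBE.
    """
    _check_dbe_elements(f)
    return 1.0 + f["C"] - (f["H"] + f["F"] + f["Cl"]) / 2.0 + f["N"] / 2.0


def aromaticity_index(f: MolecularFormula) -> float:
    """Koch–Dittmar aromaticity index with halogens counted as hydrogens.

    AI = (1 + C - O - S - 0.5·(H + F + Cl)) / (C - O - S - N), clamped to 0
    when the numerator is negative or the denominator is ≤ 0.
    """
    _check_dbe_elements(f)
    num = 1.0 + f["C"] - f["O"] - f["S"] - 0.5 * (f["H"] + f["F"] + f["Cl"])
    den = f["C"] - f["O"] - f["S"] - f["N"]
    if den <= 0:
        return 0.0
    return max(0.0, num / den)
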