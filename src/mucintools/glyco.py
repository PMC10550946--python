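"""Monosaccharide composition algebra for mucin-type O-glycans.

O-glycan compositions are described by counts of four monosaccharide
residues using the single-letter codes common in O-glycoproteomics:

* ``N`` – HexNAc (GalNAc in the mucin context), residue formula C8H13NO5
* ``H`` – hexose (galactose), C6H10O5
* ``A`` – NeuAc (sialic acid), C11H17NO8
* ``F`` – fucose (deoxyhexose), C6H10O4

Only monosaccharide *composition* is modelled; linkage and topology are
out of scope.  Compositions are classified into the O-glycan core
families (Tn, core 1, core 2, "other") used when aggregating glycopeptide
abundances per site.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "MONOSACCHARIDE_FORMULAS",
    "MONOSACCHARIDE_MASSES",
    "DEFAULT_BOUNDS",
    "DEFAULT_GLYCAN_DATABASE",
    "GlycanComposition",
    "CoreCategory",
    "CompositionParseError",
    "parse_composition",
    "composition_mass",
    "enumerate_compositions",
    "classify_core",
    "decompose_multisite",
]

#: Residue (dehydrated monomer) elemental formulas.
MONOSACCHARIDE_FORMULAS: Mapping[str, str] = {
    "N": "C8H13NO5",   # HexNAc
    "H": "C6H10O5",    # Hex
    "A": "C11H17NO8",  # NeuAc
    "F": "C6H10O4",    # dHex / fucose
}

#: Monoisotopic residue masses in Da, computed from the formulas above.
MONOSACCHARIDE_MASSES: Mapping[str, float] = {
    letter: _pmass.calculate_mass(formula=f)
    for letter, f in MONOSACCHARIDE_FORMULAS.items()
}

#: Default per-monosaccharide count ceilings for residual-mass enumeration.
#: Generous enough to cover every structure in the default glycan database.
DEFAULT_BOUNDS: Mapping[str, int] = {"N": 6, "H": 6, "A": 4, "F": 3}

#: Default enumeration tolerance in Da.
DEFAULT_TOLERANCE = 0.02

_LETTER_ORDER = ("N", "H", "A", "F")
_FIELD_BY_LETTER = {"N": "n_hexnac", "H": "n_hex", "A": "n_neuac", "F": "n_fuc"}


class CompositionParseError(ValueError):
    """Raised when a composition string does not match the N/H/A/F grammar."""


class CoreCategory(enum.Enum):
    """O-glycan core family used for per-site abundance aggregation."""

    TN = "Tn"
    CORE1 = "core1"
    CORE2 = "core2"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Deterministic category order used for tie-breaking.
CATEGORY_ORDER = (CoreCategory.TN, CoreCategory.CORE1, CoreCategory.CORE2, CoreCategory.OTHER)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of HexNAc (N), Hex (H), NeuAc (A) and Fuc (F) residues.

    The all-zero composition is the "no glycan" element; it is allowed
    everywhere except core classification.
    """

    n_hexnac: int = 0
    n_hex: int = 0
    n_neuac: int = 0
    n_fuc: int = 0

    def __post_init__(self) -> None:
        for field in ("n_hexnac", "n_hex", "n_neuac", "n_fuc"):
            v = getattr(self, field)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{field} must be a non-negative integer, got {v!r}")

    # -- count access -------------------------------------------------
    def count(self, letter: str) -> int:
        return getattr(self, _FIELD_BY_LETTER[letter])

    @property
    def total_residues(self) -> int:
        return self.n_hexnac + self.n_hex + self.n_neuac + self.n_fuc

    @property
    def is_zero(self) -> bool:
        return self.total_residues == 0

    # -- algebra ------------------------------------------------------
    @property
    def mass(self) -> float:
        """Monoisotopic residue mass in Da (zero for the empty composition)."""
        return composition_mass(self)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.n_hexnac + other.n_hexnac,
            self.n_hex + other.n_hex,
            self.n_neuac + other.n_neuac,
            self.n_fuc + other.n_fuc,
        )

    def __mul__(self, k: int) -> "GlycanComposition":
        return GlycanComposition(self.n_hexnac * k, self.n_hex * k, self.n_neuac * k, self.n_fuc * k)

    __rmul__ = __mul__

    def divide(self, k: int) -> "GlycanComposition | None":
        """Exact division by ``k``; ``None`` when any count is not divisible."""
        counts = (self.n_hexnac, self.n_hex, self.n_neuac, self.n_fuc)
        if k < 1 or any(c % k for c in counts):
            return None
        return GlycanComposition(*(c // k for c in counts))

    def strip_neuac(self) -> "GlycanComposition":
        """Composition after sialidase treatment (all NeuAc removed)."""
        return GlycanComposition(self.n_hexnac, self.n_hex, 0, self.n_fuc)

    # -- formatting ---------------------------------------------------
    def to_string(self) -> str:
        """Canonical string: order N, H, A, F; zero counts omitted; '' if empty."""
        return "".join(
            f"{letter}{self.count(letter)}" for letter in _LETTER_ORDER if self.count(letter)
        )

    def __str__(self) -> str:
        return self.to_string() or "-"

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        return parse_composition(text)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"H1N1A1"``.

    Grammar: a letter from {H, N, A, F} followed by a non-negative integer,
    in any order, each letter at most once.  The empty string denotes the
    zero composition.
    """
    counts = {letter: 0 for letter in _LETTER_ORDER}
    seen = set()
    i = 0
    text = text.strip()
    while i < len(text):
        letter = text[i]
        if letter not in counts:
            raise CompositionParseError(f"unknown monosaccharide letter {letter!r} in {text!r}")
        if letter in seen:
            raise CompositionParseError(f"duplicate monosaccharide letter {letter!r} in {text!r}")
        seen.add(letter)
        j = i + 1
        while j < len(text) and text[j].isdigit():
            j += 1
        if j == i + 1:
            raise CompositionParseError(f"missing count after {letter!r} in {text!r}")
        counts[letter] = int(text[i + 1 : j])
        i = j
    return GlycanComposition(counts["N"], counts["H"], counts["A"], counts["F"])


def composition_mass(comp: GlycanComposition) -> float:
    """Monoisotopic mass of a composition in Da (sum of residue masses)."""
    return sum(comp.count(letter) * MONOSACCHARIDE_MASSES[letter] for letter in _LETTER_ORDER)


def enumerate_compositions(
    residual_mass: float,
    tol: float = DEFAULT_TOLERANCE,
    bounds: Mapping[str, int] | None = None,
) -> list[GlycanComposition]:
    """All bounded compositions whose mass lies within ``±tol`` of ``residual_mass``.

    Sorted by absolute mass error, then canonical string.  An exactly-zero
    residual returns the empty composition; nothing matching returns ``[]``.
    """
    if residual_mass < 0 and residual_mass < -tol:
        return []
    if tol <= 0:
        raise ValueError("tol must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    hits = []
    for n, h, a, f in itertools.product(
        range(b["N"] + 1), range(b["H"] + 1), range(b["A"] + 1), range(b["F"] + 1)
    ):
        comp = GlycanComposition(n, h, a, f)
        err = abs(comp.mass - residual_mass)
        if err <= tol:
            hits.append((err, comp.to_string(), comp))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [comp for _, _, comp in hits]


def classify_core(comp: GlycanComposition) -> CoreCategory:
    """Map a non-empty composition onto its O-glycan core family.

    * Tn: a single HexNAc, optionally carrying one NeuAc *or* one Fuc
      (sialyl-/fucosyl-Tn), no Hex.
    * core 1: single HexNAc extended by Hex.
    * core 2: a second HexNAc branch (N >= 2) with Hex present.
    * other: everything else (e.g. multiple HexNAc without Hex).
    """
    if comp.is_zero:
        raise ValueError("the empty composition has no core category")
    n, h, a, f = comp.n_hexnac, comp.n_hex, comp.n_neuac, comp.n_fuc
    if n == 1 and h == 0 and a + f <= 1:
        return CoreCategory.TN
    if n == 1 and h >= 1:
        return CoreCategory.CORE1
    if n >= 2 and h >= 1:
        return CoreCategory.CORE2
    return CoreCategory.OTHER


def decompose_multisite(
    comp: GlycanComposition,
    n_unresolved_sites: int,
    has_407: bool,
    ratio_138_144: float,
) -> list[GlycanComposition] | None:
    """Split an unlocalized composition over equal sites when the spectrum
    indicates simple (core-1-or-smaller) glycans.

    A composition spanning ``n_unresolved_sites`` sites is assigned as ``n``
    identical structures (e.g. N2 over two sites becomes two N1) only when
    the 138.055/144.07 oxonium ratio is strictly under 1.2 (indicating core 1
    type fragmentation), no 407 m/z HexNAc2 oxonium is present (which would
    indicate both HexNAcs on a single site), and the equal parts classify as
    Tn or core 1.  Returns ``None`` ("keep single") otherwise.
    """
    if n_unresolved_sites < 1:
        raise ValueError("n_unresolved_sites must be >= 1")
    if n_unresolved_sites == 1:
        return [comp]
    if has_407 or not ratio_138_144 < 1.2:
        return None
    part = comp.divide(n_unresolved_sites)
    if part is None:
        warnings.warn(
            f"composition {comp} not divisible over {n_unresolved_sites} sites; keeping single",
            stacklevel=2,
        )
        return None
    if part.is_zero:
        return None
    if classify_core(part) not in (CoreCategory.TN, CoreCategory.CORE1):
        return None
    return [part] * n_unresolved_sites


def _db(*strings: str) -> tuple[GlycanComposition, ...]:
    return tuple(parse_composition(s) for s in strings)


#: Default database of 12 common O-glycan compositions used by the
#: synthetic-data generators and bundled as ``data/glycan_database.csv``.
DEFAULT_GLYCAN_DATABASE: tuple[GlycanComposition, ...] = _db(
    "N1",
    "N1A1",
    "N1F1",
    "H1N1",
    "H1N1F1",
    "H1N1A1",
    "H1N1A2",
    "N2",
    "H1N2",
    "H2N2",
    "H2N2A1",
    "H2N2A2",
)


def iter_database(db: Iterable[GlycanComposition] | None = None):
    yield from (db if db is not None else DEFAULT_GLYCAN_DATABASE)
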