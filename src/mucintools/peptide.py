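"""Glycopeptide data model and mass bookkeeping.

Peptide residue masses come from the standard monoisotopic table
(pyteomics); modifications follow the conventions of the O-glycopeptide
search setup being reproduced: carbamidomethyl Cys is a fixed
modification, Met oxidation a variable one, and O-glycans are attached to
Ser/Thr side chains as residue-mass deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _pmass

from .glyco import GlycanComposition

__all__ = [
    "PROTON",
    "WATER",
    "NH3",
    "CARBAMIDOMETHYL",
    "MET_OXIDATION",
    "MET_OX_SIDECHAIN_LOSS",
    "ISOTOPE_SPACING",
    "residue_mass",
    "peptide_neutral_mass",
    "Glycopeptide",
]

PROTON = 1.007276466  # Da, mass of a proton
WATER = _pmass.calculate_mass(formula="H2O")
NH3 = _pmass.calculate_mass(formula="NH3")
#: NH2 group; the z-dot ion m/z is the y ion minus this value.
NH2 = _pmass.calculate_mass(formula="NH2")
CARBAMIDOMETHYL = _pmass.calculate_mass(formula="C2H3NO")   # fixed on Cys
MET_OXIDATION = _pmass.calculate_mass(formula="O")          # variable on Met
#: Neutral loss of the oxidized-Met side chain (CH4SO, methanesulfenic acid).
MET_OX_SIDECHAIN_LOSS = _pmass.calculate_mass(formula="CH4SO")
#: C13 - C12 spacing used for isotope XIC channels.
ISOTOPE_SPACING = 1.00335

_AA_MASS = dict(_pmass.std_aa_mass)


def residue_mass(aa: str) -> float:
    """Monoisotopic residue mass of one amino acid (no modifications)."""
    try:
        return _AA_MASS[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def peptide_neutral_mass(
    sequence: str,
    oxidized_met: frozenset[int] | set[int] = frozenset(),
) -> float:
    """Neutral monoisotopic mass of an (unglycosylated) peptide.

    Carbamidomethyl is applied to every Cys; ``oxidized_met`` holds 1-based
    positions of oxidized Met residues.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    m = sum(residue_mass(aa) for aa in sequence) + WATER
    m += CARBAMIDOMETHYL * sequence.count("C")
    for pos in oxidized_met:
        if sequence[pos - 1] != "M":
            raise ValueError(f"oxidation at position {pos} is not on Met")
        m += MET_OXIDATION
    return m


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide with per-site O-glycan assignments.

    ``site_glycans`` maps 1-based positions within the peptide (which must
    be Ser or Thr) to glycan compositions.  ``protein_offset`` is the
    1-based start of the peptide in its parent protein.
    """

    sequence: str
    site_glycans: Mapping[int, GlycanComposition] = field(default_factory=dict)
    oxidized_met: frozenset[int] = frozenset()
    protein_offset: int = 1
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for pos, comp in self.site_glycans.items():
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"glycan position {pos} outside peptide")
            if self.sequence[pos - 1] not in "ST":
                raise ValueError(
                    f"glycan at position {pos} is on {self.sequence[pos - 1]!r}, not S/T"
                )
            if comp.is_zero:
                raise ValueError(f"zero composition assigned at position {pos}")
        object.__setattr__(self, "site_glycans", dict(self.site_glycans))
        object.__setattr__(self, "oxidized_met", frozenset(self.oxidized_met))

    # -- masses -------------------------------------------------------
    @property
    def naked_mass(self) -> float:
        """Neutral mass of the peptide stripped of all glycans (mods kept)."""
        return peptide_neutral_mass(self.sequence, self.oxidized_met)

    @property
    def glycan_mass(self) -> float:
        return sum(c.mass for c in self.site_glycans.values())

    @property
    def neutral_mass(self) -> float:
        return self.naked_mass + self.glycan_mass

    def mz(self, charge: int) -> float:
        if charge < 1:
            raise ValueError("charge must be >= 1")
        return (self.neutral_mass + charge * PROTON) / charge

    # -- sites ----------------------------------------------------------
    @property
    def candidate_sites(self) -> tuple[int, ...]:
        """All Ser/Thr positions (1-based, within-peptide)."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa in "ST")

    @property
    def glycan_multiset(self) -> tuple[GlycanComposition, ...]:
        """The glycans carried, sorted canonically (positions forgotten)."""
        return tuple(sorted(self.site_glycans.values(), key=lambda c: c.to_string()))

    @property
    def total_composition(self) -> GlycanComposition:
        total = GlycanComposition()
        for comp in self.site_glycans.values():
            total = total + comp
        return total

    def protein_site(self, peptide_pos: int) -> int:
        """Convert a within-peptide 1-based position to a protein position."""
        return self.protein_offset + peptide_pos - 1

    def with_sites(self, site_glycans: Mapping[int, GlycanComposition]) -> "Glycopeptide":
        return Glycopeptide(
            self.sequence, site_glycans, self.oxidized_met, self.protein_offset, self.protein_id
        )

    def __str__(self) -> str:
        marks = []
        for i, aa in enumerate(self.sequence, start=1):
            if i in self.site_glycans:
                marks.append(f"{aa}[{self.site_glycans[i]}]")
            elif i in self.oxidized_met:
                marks.append(f"{aa}(ox)")
            else:
                marks.append(aa)
        return "".join(marks)
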