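"""Glycoproteomic landscape accounting and cleavage-motif analysis.

Maps validated glycopeptides back onto protein sequences, records
O-glycoprotease cleavage events (by the P1' residue index, i.e. the
residue immediately C-terminal to the scissile bond), counts localized
and implied glycosites, mapped glycan structures and unique glycoforms,
computes enzyme overlaps, and builds ±k sequence windows around cleavage
sites together with the position frequency matrix and the P1/P1' glycan
distributions used for consensus-motif logos.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .glyco import GlycanComposition

__all__ = [
    "AMINO_ACIDS",
    "CleavageEvent",
    "MappedPeptide",
    "LandscapeSummary",
    "map_peptide",
    "cleavage_sites",
    "glycosite_counts",
    "count_structures_and_glycoforms",
    "enzyme_overlap",
    "motif_windows",
    "MotifResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class CleavageEvent:
    """One scissile bond, recorded by the 1-based index of its P1' residue."""

    protein_id: str
    position: int
    enzyme: str

    def __post_init__(self) -> None:
        if self.position < 2:
            raise ValueError("cleavage position must be >= 2 (bond requires a P1 residue)")


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide with its exact-match start positions in a protein."""

    protein_id: str
    sequence: str
    starts: tuple[int, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.starts) > 1

    @property
    def unmapped(self) -> bool:
        return len(self.starts) == 0


def map_peptide(protein: str, peptide: str) -> list[int]:
    """All 1-based exact occurrences of ``peptide`` in ``protein``."""
    if not protein or not peptide:
        raise ValueError("empty sequence")
    hits = []
    start = protein.find(peptide)
    while start != -1:
        hits.append(start + 1)
        start = protein.find(peptide, start + 1)
    return hits


def cleavage_sites(
    protein_id: str,
    protein: str,
    mapped: Iterable[MappedPeptide],
    enzyme: str,
    trypsin_used: bool = False,
) -> set[CleavageEvent]:
    """Cleavage events implied by unambiguously mapped peptide boundaries.

    The N-terminal boundary of each peptide is an event unless it is the
    protein N-terminus.  The C-terminal boundary is an event when the next
    residue starts another observed peptide or is Ser/Thr.  When trypsin
    was used in the digest, boundaries C-terminal to Lys/Arg are excluded
    (they are tryptic, not O-glycoprotease, cuts).
    """
    mapped = [m for m in mapped if not m.ambiguous and not m.unmapped]
    starts = {m.starts[0] for m in mapped}
    events: set[CleavageEvent] = set()
    for m in mapped:
        start = m.starts[0]
        end = start + len(m.sequence) - 1        # last residue index
        if start > 1 and not (trypsin_used and protein[start - 2] in "KR"):
            events.add(CleavageEvent(protein_id, start, enzyme))
        nxt = end + 1
        if nxt <= len(protein) and not (trypsin_used and protein[end - 1] in "KR"):
            if nxt in starts or protein[nxt - 1] in "ST":
                events.add(CleavageEvent(protein_id, nxt, enzyme))
    return events


def glycosite_counts(
    localized_sites: Iterable[tuple[str, int]],
    events: Iterable[CleavageEvent],
    proteins: Mapping[str, str],
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """(localized, implied) glycosite sets.

    Implied glycosites are Ser/Thr residues found at the P1' position of a
    cleavage event but never themselves localized by MS.
    """
    localized = set(localized_sites)
    implied: set[tuple[str, int]] = set()
    for ev in events:
        seq = proteins.get(ev.protein_id)
        if seq is None or ev.position > len(seq):
            continue
        key = (ev.protein_id, ev.position)
        if seq[ev.position - 1] in "ST" and key not in localized:
            implied.add(key)
    return localized, implied


def count_structures_and_glycoforms(
    validated: Iterable[
        tuple[str, str, Mapping[int, GlycanComposition], Sequence[GlycanComposition]]
    ],
) -> tuple[int, int]:
    """(mapped glycan structures, unique glycoforms).

    Input tuples: (protein_id, peptide sequence, localized protein-site ->
    glycan map, full glycan multiset of the peptide).  Mapped structures
    count distinct (site, glycan) pairs; unique glycoforms count distinct
    (peptide sequence, glycan multiset, localization pattern) triples, so
    unlocalized variants of the same composition collapse.
    """
    structures: set[tuple[str, int, str]] = set()
    glycoforms: set[tuple[str, str, tuple, tuple]] = set()
    for protein_id, sequence, site_map, multiset in validated:
        for site, glycan in site_map.items():
            structures.add((protein_id, site, glycan.to_string()))
        loc_pattern = tuple(sorted((s, g.to_string()) for s, g in site_map.items()))
        composition = tuple(sorted(g.to_string() for g in multiset))
        glycoforms.add((protein_id, sequence, composition, loc_pattern))
    return len(structures), len(glycoforms)


def enzyme_overlap(sets_by_enzyme: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Sizes of all pairwise and higher-order intersections (Euler-plot data)."""
    import itertools

    names = sorted(sets_by_enzyme)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets_by_enzyme[n] for n in combo))
            out[combo] = len(inter)
    return out


@dataclass
class MotifResult:
    """Aligned cleavage windows with the derived frequency matrix."""

    windows: list[str]
    #: positions P{k}..P1, P1'..P{k}' as columns; rows = amino acids + gap
    frequency: pd.DataFrame
    p1_glycans: Counter = field(default_factory=Counter)
    p1prime_glycans: Counter = field(default_factory=Counter)

    @property
    def positions(self) -> list[str]:
        return list(self.frequency.columns)


def motif_windows(
    proteins: Mapping[str, str],
    events: Iterable[CleavageEvent],
    k: int = 5,
    site_glycans: Mapping[tuple[str, int], GlycanComposition] | None = None,
) -> MotifResult:
    """±k residue windows around each cleavage site plus summary tallies.

    Windows run P{k}..P1 then P1'..P{k}' and are gap-padded at protein
    termini.  The frequency matrix columns each sum to 1 over the 20 amino
    acids plus the gap symbol.  When per-(protein, site) glycans are given,
    the P1 and P1' glycan distributions (motif pie-chart data) are tallied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positions = [f"P{i}" for i in range(k, 0, -1)] + [f"P{i}'" for i in range(1, k + 1)]
    windows: list[str] = []
    counts = {pos: Counter() for pos in positions}
    p1_glycans: Counter = Counter()
    p1p_glycans: Counter = Counter()
    for ev in events:
        seq = proteins[ev.protein_id]
        window = []
        for offset in range(-k, k):
            idx = ev.position + offset          # 1-based residue index
            window.append(seq[idx - 1] if 1 <= idx <= len(seq) else GAP)
        windows.append("".join(window))
        for pos, aa in zip(positions, window):
            counts[pos][aa] += 1
        if site_glycans is not None:
            g1 = site_glycans.get((ev.protein_id, ev.position - 1))
            g1p = site_glycans.get((ev.protein_id, ev.position))
            p1_glycans[g1.to_string() if g1 else "none"] += 1
            p1p_glycans[g1p.to_string() if g1p else "none"] += 1
    letters = list(AMINO_ACIDS) + [GAP]
    n = max(len(windows), 1)
    freq = pd.DataFrame(
        {pos: [counts[pos][aa] / n for aa in letters] for pos in positions}, index=letters
    )
    return MotifResult(windows, freq, p1_glycans, p1p_glycans)


@dataclass
class LandscapeSummary:
    """Headline counts for one enzyme's digest of a protein panel."""

    enzyme: str
    n_cleavage_sites: int
    n_localized_glycosites: int
    n_implied_glycosites: int
    n_mapped_structures: int
    n_unique_glycoforms: int

    @property
    def n_total_glycosites(self) -> int:
        return self.n_localized_glycosites + self.n_implied_glycosites

    def to_dict(self) -> dict:
        return {
            "enzyme": self.enzyme,
            "cleavage_sites": self.n_cleavage_sites,
            "localized_glycosites": self.n_localized_glycosites,
            "implied_glycosites": self.n_implied_glycosites,
            "total_glycosites": self.n_total_glycosites,
            "mapped_structures": self.n_mapped_structures,
            "unique_glycoforms": self.n_unique_glycoforms,
        }
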