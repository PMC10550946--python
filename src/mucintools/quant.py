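"""XIC label-free quantitation of validated glycopeptides.

Abundances are areas under extracted ion chromatograms (XICs).  The
number of isotope channels integrated depends on the neutral mass (one
below 1600 Da, two up to 2400 Da, three above), all observed charge
states are summed, and per-site glycan aggregation first picks the most
abundant core category (Tn, core 1, core 2, other) and then the most
abundant glycan within it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glyco import CATEGORY_ORDER, CoreCategory, GlycanComposition, classify_core
from .peptide import ISOTOPE_SPACING, PROTON, Glycopeptide

__all__ = [
    "ChromatographicTrace",
    "Ms1Run",
    "SiteQuantRecord",
    "isotopes_for_mass",
    "xic_auc",
    "glycoform_abundance",
    "site_glycan_table",
    "most_abundant_glycan_per_site",
]

MS1_TOL_PPM = 10.0
RT_PAD_MIN = 0.5


@dataclass
class ChromatographicTrace:
    """An MS1 intensity trace on one m/z channel: times strictly increasing."""

    retention_times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.retention_times.shape != self.intensities.shape:
            raise ValueError("length mismatch between times and intensities")
        if np.any(np.diff(self.retention_times) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.retention_times[0]), float(self.retention_times[-1])


def isotopes_for_mass(neutral_mass: float) -> list[int]:
    """Isotope indices to integrate for a given neutral mass.

    Below 1600 Da only the 12C (monoisotopic) peak; up to and including
    2400 Da also the first 13C isotope; above 2400 Da three isotopes.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if neutral_mass < 1600.0:
        return [0]
    if neutral_mass <= 2400.0:
        return [0, 1]
    return [0, 1, 2]


def xic_auc(trace: ChromatographicTrace, rt_window: tuple[float, float]) -> float:
    """Trapezoidal area of a trace over an RT window (intensity * min)."""
    lo, hi = rt_window
    if hi < lo:
        raise ValueError(f"inverted RT window {rt_window}")
    t, y = trace.retention_times, trace.intensities
    lo = max(lo, t[0])
    hi = min(hi, t[-1])
    if hi <= lo:
        return 0.0
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    yy = np.concatenate(([np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]))
    return float(np.trapezoid(yy, tt))


@dataclass
class Ms1Run:
    """A collection of per-channel MS1 traces keyed by (channel m/z, charge).

    ``etd_method`` marks the file acquired with the plain-ETD method;
    when several runs quantify the same glycoform the ETD file wins.
    """

    channels: dict[tuple[float, int], ChromatographicTrace] = field(default_factory=dict)
    etd_method: bool = True

    def add_channel(self, mz: float, charge: int, trace: ChromatographicTrace) -> None:
        self.channels[(float(mz), int(charge))] = trace

    def find_channel(
        self, mz: float, charge: int, tol_ppm: float = MS1_TOL_PPM
    ) -> ChromatographicTrace | None:
        tol = mz * tol_ppm * 1e-6
        best, best_err = None, tol
        for (cmz, cz), trace in self.channels.items():
            if cz == charge and abs(cmz - mz) <= best_err:
                best, best_err = trace, abs(cmz - mz)
        return best

    @property
    def observed_charges(self) -> tuple[int, ...]:
        return tuple(sorted({z for _, z in self.channels}))

    # -- I/O ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mz, z), trace in sorted(self.channels.items()):
            for t, y in zip(trace.retention_times, trace.intensities):
                rows.append((mz, z, t, y))
        return pd.DataFrame(rows, columns=["channel_mz", "charge", "rt", "intensity"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, etd_method: bool = True) -> "Ms1Run":
        run = cls(etd_method=etd_method)
        for (mz, z), grp in df.groupby(["channel_mz", "charge"], sort=True):
            grp = grp.sort_values("rt")
            run.add_channel(
                float(mz), int(z),
                ChromatographicTrace(grp["rt"].to_numpy(), grp["intensity"].to_numpy()),
            )
        return run

    @classmethod
    def from_csv(cls, path, etd_method: bool = True) -> "Ms1Run":
        return cls.from_frame(pd.read_csv(path), etd_method=etd_method)


def glycoform_abundance(
    run: Ms1Run,
    gp: Glycopeptide,
    rt_window: tuple[float, float],
    charges: Iterable[int] | None = None,
    tol_ppm: float = MS1_TOL_PPM,
) -> float:
    """Summed XIC area of a glycoform over isotope channels and charges.

    Channels are placed at ``(M + k*1.00335 + z*proton)/z`` for the isotope
    indices selected by :func:`isotopes_for_mass`; all observed charge
    states contribute.
    """
    mass = gp.neutral_mass
    isotopes = isotopes_for_mass(mass)
    if charges is None:
        charges = run.observed_charges
    total = 0.0
    found = 0
    for z in charges:
        for k in isotopes:
            mz = (mass + k * ISOTOPE_SPACING + z * PROTON) / z
            trace = run.find_channel(mz, z, tol_ppm)
            if trace is None:
                continue
            found += 1
            total += xic_auc(trace, rt_window)
    if found == 0:
        import warnings

        warnings.warn(f"no MS1 channels found for {gp}", stacklevel=2)
    return total


@dataclass(frozen=True)
class SiteQuantRecord:
    """Per-(protein, site, glycan) abundance with its within-site fraction."""

    protein_id: str
    site: int                       # 1-based residue index in the protein
    glycan: GlycanComposition
    auc: float
    relative_abundance: float

    @property
    def category(self) -> CoreCategory:
        return classify_core(self.glycan)


def site_glycan_table(
    records: Iterable[tuple[str, int, GlycanComposition, float]],
) -> list[SiteQuantRecord]:
    """Aggregate glycoform AUCs into per-(protein, site, glycan) records.

    Input tuples are (protein_id, protein site, glycan, auc) — one per
    validated glycoform containing that localized site.  AUCs of all
    peptides sharing a (site, glycan) pair are summed; relative abundances
    are normalized per site.
    """
    sums: dict[tuple[str, int, GlycanComposition], float] = {}
    for protein_id, site, glycan, auc in records:
        if auc < 0:
            raise ValueError("negative AUC")
        key = (protein_id, site, glycan)
        sums[key] = sums.get(key, 0.0) + auc
    site_totals: dict[tuple[str, int], float] = {}
    for (protein_id, site, _), auc in sums.items():
        site_totals[(protein_id, site)] = site_totals.get((protein_id, site), 0.0) + auc
    out = []
    for (protein_id, site, glycan), auc in sorted(
        sums.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].to_string())
    ):
        total = site_totals[(protein_id, site)]
        rel = auc / total if total > 0 else 0.0
        out.append(SiteQuantRecord(protein_id, site, glycan, auc, rel))
    return out


def records_to_frame(records: Sequence[SiteQuantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.protein_id, r.site, r.glycan.to_string(), str(r.category), r.auc, r.relative_abundance)
            for r in records
        ],
        columns=["protein_id", "site", "glycan", "category", "auc", "relative_abundance"],
    )


def most_abundant_glycan_per_site(
    records: Iterable[SiteQuantRecord],
) -> dict[tuple[str, int], GlycanComposition]:
    """Category-first winner per site.

    The core category with the largest combined area wins, then the
    most abundant glycan within that category.  Exact ties are broken by
    the fixed category order (Tn < core 1 < core 2 < other) and by
    canonical composition string, so the result is deterministic.
    """
    by_site: dict[tuple[str, int], list[SiteQuantRecord]] = {}
    for r in records:
        by_site.setdefault((r.protein_id, r.site), []).append(r)
    winners: dict[tuple[str, int], GlycanComposition] = {}
    for key, recs in by_site.items():
        cat_total: dict[CoreCategory, float] = {}
        for r in recs:
            cat_total[r.category] = cat_total.get(r.category, 0.0) + r.auc
        best_cat = min(
            cat_total,
            key=lambda c: (-cat_total[c], CATEGORY_ORDER.index(c)),
        )
        in_cat = [r for r in recs if r.category is best_cat]
        winner = min(in_cat, key=lambda r: (-r.auc, r.glycan.to_string()))
        winners[key] = winner.glycan
    return winners
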