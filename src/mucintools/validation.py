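"""Deterministic glycopeptide validation engine.

This module encodes, as an explicit rulebook, the manual curation
procedure used for mucinase-derived O-glycopeptides:

1. *Naked-peptide rule* — the HCD spectrum must contain the intact
   peptide stripped of glycans (Y0) at some charge; for oxidized-Met
   peptides the Y0 minus the Met side-chain loss also counts.
2. *Backbone-coverage rule* — short peptides need nearly full glycan-free
   b/y coverage; long peptides need the bonds expected to fragment
   abundantly (N-terminal to Pro, C-terminal to Asp); a C-terminal Pro is
   satisfied by b(n-1) alone.
3. *Localization* — glycan-retaining c/z ions from ETD/EThcD are tested
   against every arrangement of the glycan multiset over candidate Ser/Thr
   sites; a site is localized when all evidence-consistent arrangements
   agree on its glycan.
4. *Multi-site decomposition* — when localization fails, a composition
   such as N2 over two sites is split into two N1 structures provided the
   138/144 oxonium ratio is under 1.2 and no 407 m/z HexNAc2 oxonium is
   present.

Identification transfer to weaker spectra of the same naked peptide uses
cosine similarity over the strong spectrum's matched backbone channels.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .glyco import GlycanComposition, decompose_multisite, enumerate_compositions
from .peptide import MET_OX_SIDECHAIN_LOSS, PROTON, Glycopeptide, peptide_neutral_mass
from .spectra import (
    OXONIUM_HEXNAC,
    OXONIUM_HEXNAC2,
    Activation,
    FragmentMatch,
    Spectrum,
    fingerprint_ratio,
    match_peaks,
    should_trigger_etd,
    theoretical_fragments,
)

__all__ = [
    "SiteStatus",
    "Status",
    "RuleResult",
    "ValidationConfig",
    "ValidationDecision",
    "check_naked_peptide",
    "check_backbone_coverage",
    "localize_glycans",
    "find_candidate_scans",
    "residual_match",
    "transfer_identification",
    "average_spectra",
    "validate",
]


class Status(enum.Enum):
    ACCEPT = "accept"
    REJECT = "reject"
    AMBIGUOUS = "ambiguous"


class SiteStatus(enum.Enum):
    LOCALIZED = "localized"
    UNLOCALIZED = "unlocalized"
    CONTRADICTED = "contradicted"


@dataclass(frozen=True)
class RuleResult:
    rule: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationConfig:
    tol_ppm: float = 20.0                # MS2 tolerance
    short_peptide_max_len: int = 12      # "nearly full coverage" applies up to here
    coverage_threshold: float = 0.8      # fraction of backbone bonds
    min_similarity: float = 0.7          # spectral-transfer cosine threshold
    candidate_floor_rel: float = 0.05    # 204 extraction intensity floor
    max_arrangements: int = 50000


@dataclass
class ValidationDecision:
    status: Status
    reasons: list[RuleResult]
    site_status: dict[int, SiteStatus]
    assigned_site_glycans: dict[int, GlycanComposition] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.status is Status.ACCEPT

    def localized_sites(self) -> tuple[int, ...]:
        return tuple(s for s, st in sorted(self.site_status.items()) if st is SiteStatus.LOCALIZED)


# ----------------------------------------------------------------------
# Rule 1: naked peptide (Y0)
# ----------------------------------------------------------------------

def check_naked_peptide(
    gp: Glycopeptide, hcd: Spectrum, tol_ppm: float = 20.0
) -> RuleResult:
    """Y0 (or Y0 minus the oxidized-Met side-chain loss) at any charge."""
    naked = gp.naked_mass
    targets = [naked]
    if gp.oxidized_met:
        targets.append(naked - MET_OX_SIDECHAIN_LOSS)
    for neutral in targets:
        for z in range(1, max(1, hcd.precursor_charge) + 1):
            mz = (neutral + z * PROTON) / z
            if hcd.has_peak_near(mz, mz * tol_ppm * 1e-6):
                which = "Y0" if neutral == naked else "Y0-CH4SO"
                return RuleResult("naked_peptide", True, f"{which} at z={z} ({mz:.4f})")
    return RuleResult("naked_peptide", False, "no Y0-related peak")


# ----------------------------------------------------------------------
# Rule 2: backbone coverage
# ----------------------------------------------------------------------

def _covered_bonds(n: int, matches: Iterable[FragmentMatch]) -> set[int]:
    covered: set[int] = set()
    for m in matches:
        if not m.ion.glycan_retained.is_zero:
            continue
        if m.series == "b" and 1 <= m.index <= n - 1:
            covered.add(m.index)
        elif m.series == "y" and 1 <= m.index <= n - 1:
            covered.add(n - m.index)
    return covered


def expected_abundant_bonds(sequence: str) -> set[int]:
    """Bonds N-terminal to Pro and C-terminal to Asp (1-based bond index)."""
    n = len(sequence)
    bonds: set[int] = set()
    for i, aa in enumerate(sequence, start=1):
        if aa == "P" and i >= 2:
            bonds.add(i - 1)
        if aa == "D" and i <= n - 1:
            bonds.add(i)
    return bonds


def check_backbone_coverage(
    gp: Glycopeptide,
    matches: Sequence[FragmentMatch],
    config: ValidationConfig = ValidationConfig(),
) -> tuple[RuleResult, float]:
    """Coverage rule; returns (result, fraction of backbone bonds covered)."""
    n = len(gp.sequence)
    if n < 2:
        return RuleResult("backbone_coverage", False, "peptide too short"), 0.0
    covered = _covered_bonds(n, matches)
    fraction = len(covered) / (n - 1)
    if n <= config.short_peptide_max_len:
        ok = fraction >= config.coverage_threshold
        return (
            RuleResult(
                "backbone_coverage", ok, f"coverage {fraction:.2f} (threshold {config.coverage_threshold})"
            ),
            fraction,
        )
    required = expected_abundant_bonds(gp.sequence)
    if not required:
        # no Pro/Asp anchors: fall back to the fractional rule
        ok = fraction >= config.coverage_threshold
        return (
            RuleResult("backbone_coverage", ok, f"no Pro/Asp anchors; coverage {fraction:.2f}"),
            fraction,
        )
    missing = sorted(required - covered)
    ok = not missing
    detail = "all expected-abundant bonds covered" if ok else f"missing bonds {missing}"
    return RuleResult("backbone_coverage", ok, detail), fraction


# ----------------------------------------------------------------------
# Rule 3: c/z site localization by arrangement enumeration
# ----------------------------------------------------------------------

def _arrangements(
    sites: Sequence[int], glycans: Sequence[GlycanComposition], limit: int
) -> list[dict[int, GlycanComposition]]:
    """Distinct placements of the glycan multiset over candidate sites."""
    if len(glycans) > len(sites):
        raise ValueError("more glycans than candidate sites")
    padded = tuple(glycans) + (None,) * (len(sites) - len(glycans))
    seen: set[tuple] = set()
    out: list[dict[int, GlycanComposition]] = []
    for perm in itertools.permutations(padded):
        if perm in seen:
            continue
        seen.add(perm)
        out.append({s: g for s, g in zip(sites, perm) if g is not None})
        if len(out) > limit:
            raise ValueError(f"arrangement enumeration exceeds limit {limit}")
    return out


def localize_glycans(
    gp: Glycopeptide,
    etd: Spectrum | None,
    config: ValidationConfig = ValidationConfig(),
) -> tuple[dict[int, SiteStatus], dict[int, GlycanComposition]]:
    """Arrangement-consistency localization from glycan-retaining c/z ions.

    Every placement of the glycan multiset over candidate S/T sites is
    generated; matched c/z ions (with the glycan they retain) form the
    evidence; an arrangement is consistent when it implies every evidence
    ion.  A site is localized iff all consistent arrangements agree on a
    (non-empty) glycan there; zero consistent arrangements mark all sites
    contradicted.  c/z evidence alone is used: glycan-stripped HCD b/y
    ions carry no positional information about the glycans.
    """
    sites = gp.candidate_sites
    glycans = gp.glycan_multiset
    if etd is None or not sites:
        return {s: SiteStatus.UNLOCALIZED for s in sites}, {}
    max_charge = max(1, etd.precursor_charge - 1)
    try:
        arrangements = _arrangements(sites, glycans, config.max_arrangements)
    except ValueError:
        # too many placements to adjudicate: leave everything unlocalized
        return {s: SiteStatus.UNLOCALIZED for s in sites}, {}

    n = len(gp.sequence)
    # naked c/z fragment masses (singly protonated neutral bases), computed once
    naked = {
        (t.series, t.index): (t.mz * 1 - 0.0, t.mz)   # m/z at z=1 == neutral + proton
        for t in theoretical_fragments(gp.with_sites({}), ("c", "z"), max_charge=1)
        if t.series in ("c", "z")
    }
    # implied retained-glycan map per arrangement, as cheap tuples
    implied: list[dict[tuple[str, int], GlycanComposition]] = []
    candidates: dict[tuple[str, int, GlycanComposition], float] = {}
    zero = GlycanComposition()
    for arr in arrangements:
        imp: dict[tuple[str, int], GlycanComposition] = {}
        running = zero
        prefix: dict[int, GlycanComposition] = {}
        for pos in range(1, n + 1):
            if pos in arr:
                running = running + arr[pos]
            prefix[pos] = running
        total = running
        for i in range(1, n):
            retained_c = prefix[i]
            retained_z = GlycanComposition(
                total.n_hexnac - retained_c.n_hexnac,
                total.n_hex - retained_c.n_hex,
                total.n_neuac - retained_c.n_neuac,
                total.n_fuc - retained_c.n_fuc,
            )
            imp[("c", i)] = retained_c
            imp[("z", n - i)] = retained_z
            candidates.setdefault(("c", i, retained_c), naked[("c", i)][1] + retained_c.mass)
            candidates.setdefault(("z", n - i, retained_z), naked[("z", n - i)][1] + retained_z.mass)
        implied.append(imp)
    # glycan-free c/z ions are evidence too: observing one where every
    # arrangement retains a glycan contradicts the assignment
    for i in range(1, n):
        candidates.setdefault(("c", i, zero), naked[("c", i)][1])
        candidates.setdefault(("z", n - i, zero), naked[("z", n - i)][1])

    evidence: set[tuple[str, int, GlycanComposition]] = set()
    for (series, index, retained), mz1 in candidates.items():
        neutral = mz1 - PROTON
        for z in range(1, max_charge + 1):
            mz = (neutral + z * PROTON) / z
            if etd.has_peak_near(mz, mz * config.tol_ppm * 1e-6):
                evidence.add((series, index, retained))
                break

    consistent = [
        arr
        for arr, imp in zip(arrangements, implied)
        if all(imp[(series, index)] == retained for series, index, retained in evidence)
    ]
    if not consistent:
        return {s: SiteStatus.CONTRADICTED for s in sites}, {}
    status: dict[int, SiteStatus] = {}
    assigned: dict[int, GlycanComposition] = {}
    for s in sites:
        values = {arr.get(s) for arr in consistent}
        if len(values) == 1:
            val = values.pop()
            if val is not None:
                status[s] = SiteStatus.LOCALIZED
                assigned[s] = val
            else:
                status[s] = SiteStatus.UNLOCALIZED
        else:
            status[s] = SiteStatus.UNLOCALIZED
    return status, assigned


# ----------------------------------------------------------------------
# Candidate-scan extraction and de novo residual matching
# ----------------------------------------------------------------------

def find_candidate_scans(
    run: Iterable[Spectrum], config: ValidationConfig = ValidationConfig()
) -> list[Spectrum]:
    """HCD scans with a 204.0867 HexNAc oxonium above the intensity floor,
    united with scans that fire the ETD trigger."""
    out = []
    for spec in run:
        if spec.activation is not Activation.HCD:
            continue
        floor = config.candidate_floor_rel * spec.base_peak_intensity
        has_204 = spec.has_peak_near(OXONIUM_HEXNAC, 0.1, min_intensity=floor)
        if has_204 or should_trigger_etd(spec)[0]:
            out.append(spec)
    return out


def residual_match(
    scan: Spectrum,
    sequence: str,
    oxidized_met: frozenset[int] | set[int] = frozenset(),
    tol: float = 0.02,
    bounds: Mapping[str, int] | None = None,
) -> list[GlycanComposition]:
    """Glycan compositions explaining precursor mass minus naked peptide mass."""
    residual = scan.precursor_neutral_mass - peptide_neutral_mass(sequence, oxidized_met)
    if residual < -tol:
        return []
    return enumerate_compositions(max(residual, 0.0), tol, bounds)


# ----------------------------------------------------------------------
# Identification transfer (manual spectral matching)
# ----------------------------------------------------------------------

def transfer_identification(
    strong: tuple[Glycopeptide, Spectrum],
    weak: Spectrum,
    min_similarity: float = 0.7,
    tol_ppm: float = 20.0,
) -> tuple[bool, float]:
    """Transfer a validated identification to a weaker spectrum of the same
    naked peptide via cosine similarity over the strong spectrum's matched
    backbone-fragment m/z channels.  Returns (accept, similarity)."""
    gp, strong_spec = strong
    theo = theoretical_fragments(
        gp, ("b", "y"), max_charge=max(1, strong_spec.precursor_charge - 1),
        precursor_charge=strong_spec.precursor_charge,
    )
    theo = [t for t in theo if t.series in ("b", "y")]
    matches = match_peaks(strong_spec, theo, tol_ppm)
    channels: dict[float, float] = {}
    for m in matches:
        channels[m.ion.mz] = max(channels.get(m.ion.mz, 0.0), m.observed_intensity)
    if not channels:
        return False, 0.0
    mzs = sorted(channels)
    v_strong = np.array([channels[mz] for mz in mzs])
    v_weak = np.empty(len(mzs))
    for i, mz in enumerate(mzs):
        tol = mz * tol_ppm * 1e-6
        lo, hi = np.searchsorted(weak.mz, (mz - tol, mz + tol))
        v_weak[i] = weak.intensity[lo:hi].max() if hi > lo else 0.0
    denom = np.linalg.norm(v_strong) * np.linalg.norm(v_weak)
    sim = float(v_strong @ v_weak / denom) if denom > 0 else 0.0
    return sim >= min_similarity, sim


# ----------------------------------------------------------------------
# Spectrum averaging (optional pre-processing)
# ----------------------------------------------------------------------

def average_spectra(spectra: Sequence[Spectrum], tol_ppm: float = 10.0) -> Spectrum:
    """Merge several MS2 scans of the same precursor by intensity-summed
    peak merging within a ppm window."""
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    for m, i in zip(mz, inten):
        if out_mz and (m - out_mz[-1]) <= out_mz[-1] * tol_ppm * 1e-6:
            total = out_int[-1] + i
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / total
            out_int[-1] = total
        else:
            out_mz.append(float(m))
            out_int.append(float(i))
    return Spectrum(
        scan_id=f"avg({','.join(s.scan_id for s in spectra)})",
        activation=ref.activation,
        precursor_mz=ref.precursor_mz,
        precursor_charge=ref.precursor_charge,
        retention_time=ref.retention_time,
        mz=np.array(out_mz),
        intensity=np.array(out_int),
    )


# ----------------------------------------------------------------------
# Full decision
# ----------------------------------------------------------------------

def validate(
    gp: Glycopeptide,
    hcd: Spectrum,
    etd: Spectrum | None = None,
    config: ValidationConfig = ValidationConfig(),
) -> ValidationDecision:
    """Combine the rulebook into a single decision.

    The naked-peptide and coverage rules are both necessary for acceptance;
    localization only affects per-site status.  When no site localizes and
    the spectrum indicates simple core 1 type glycans (138/144 < 1.2, no
    407 m/z), the composition is decomposed into equal parts over the
    unlocalized candidate sites.
    """
    reasons: list[RuleResult] = []

    naked = check_naked_peptide(gp, hcd, config.tol_ppm)
    reasons.append(naked)

    theo_by = theoretical_fragments(
        gp, ("b", "y"), max_charge=max(1, hcd.precursor_charge - 1),
        precursor_charge=hcd.precursor_charge,
    )
    hcd_matches = match_peaks(hcd, theo_by, config.tol_ppm)
    coverage, fraction = check_backbone_coverage(gp, hcd_matches, config)
    reasons.append(coverage)

    site_status, assigned = localize_glycans(gp, etd, config)
    n_localized = sum(1 for st in site_status.values() if st is SiteStatus.LOCALIZED)
    reasons.append(
        RuleResult(
            "localization",
            n_localized == len(gp.site_glycans),
            f"{n_localized}/{len(gp.site_glycans)} glycans localized",
        )
    )

    status = Status.ACCEPT if (naked.passed and coverage.passed) else Status.REJECT

    if status is Status.ACCEPT:
        unresolved = [s for s in gp.candidate_sites if site_status.get(s) is SiteStatus.UNLOCALIZED]
        remaining = gp.total_composition
        for comp in assigned.values():
            remaining = GlycanComposition(
                remaining.n_hexnac - comp.n_hexnac,
                remaining.n_hex - comp.n_hex,
                remaining.n_neuac - comp.n_neuac,
                remaining.n_fuc - comp.n_fuc,
            )
        if len(unresolved) >= 2 and not remaining.is_zero:
            ratio = fingerprint_ratio(hcd)
            has_407 = hcd.has_peak_near(OXONIUM_HEXNAC2, 0.1)
            if not math.isnan(ratio):
                parts = decompose_multisite(remaining, len(unresolved), has_407, ratio)
                if parts is not None:
                    for site, part in zip(unresolved, parts):
                        assigned[site] = part
                    reasons.append(
                        RuleResult(
                            "multisite_decomposition", True,
                            f"{remaining} split as {len(parts)} x {parts[0]}",
                        )
                    )
    return ValidationDecision(status, reasons, site_status, assigned)
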