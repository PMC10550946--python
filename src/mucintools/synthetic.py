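"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (seed, parameters) and returns the
planted ground truth alongside the observable, so downstream recovery
tests can compare against it:

* mucin glycoproteins with site-specific glycan draws,
* O-glycoprotease digests under enzyme-specific rules (SmE, ImpA, OgpA,
  StcE),
* HCD/ETD runs with oxonium fingerprints, fragment dropout and Gaussian
  MS1 elution peaks at planted abundances,
* worm-like-chain trajectories of known persistence length (the
  successive bond deflection is drawn so that its mean cosine equals
  ``exp(-lb/lp)``),
* one-phase exponential SPR decays of known rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .glyco import GlycanComposition, parse_composition
from .peptide import ISOTOPE_SPACING, PROTON, Glycopeptide
from .quant import ChromatographicTrace, Ms1Run, isotopes_for_mass
from .spectra import (
    FINGERPRINT_IONS,
    OXONIUM_HEXNAC2,
    Activation,
    Spectrum,
    should_trigger_etd,
    theoretical_fragments,
)
from .mdmetrics import PolymerTrajectory

__all__ = [
    "EnzymeRule",
    "SME",
    "IMPA",
    "OGPA",
    "STCE",
    "ENZYMES",
    "Glycoprotein",
    "make_glycoprotein",
    "digest",
    "PlantedGlycoform",
    "SyntheticRun",
    "make_run",
    "shuffled_copy",
    "make_wlc_trajectory",
    "make_spr_sensorgram",
    "write_run",
]


# ----------------------------------------------------------------------
# Enzyme rules
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage rule of an O-glycoprotease.

    ``requires_glycan_at_P1prime`` rules cut immediately N-terminal to a
    glycosylated Ser/Thr; ``p1_glycan_policy`` states whether a
    glycosylated P1 residue is tolerated (SmE) or forbids the cut (ImpA);
    ``blocked_glycan`` vetoes cuts whose P1' glycan matches a predicate
    (OgpA and sialic acid).  ``context_motif='T/S*_X_T/S'`` switches to the
    StcE rule, whose scissile bond sits C-terminal to the glycosylated P1
    residue by default (``stce_cut_after_x`` moves it past the X residue).
    """

    name: str
    requires_glycan_at_P1prime: bool = True
    p1_glycan_policy: str = "tolerated"           # or "forbidden"
    blocked_glycan: Callable[[GlycanComposition], bool] | None = None
    context_motif: str | None = None
    stce_cut_after_x: bool = False

    def cleavage_positions(self, glycoprotein: "Glycoprotein") -> list[int]:
        """1-based P1' indices of every scissile bond in the protein."""
        seq = glycoprotein.sequence
        glycans = glycoprotein.site_glycans
        positions = []
        if self.context_motif is not None:
            # T/S*_X_T/S: P1 glycosylated S/T, X anything, P2' S/T
            for p1 in sorted(glycans):
                x = p1 + 1
                p2 = p1 + 2
                if p2 <= len(seq) and seq[p1 - 1] in "ST" and seq[p2 - 1] in "ST":
                    cut = x + 1 if self.stce_cut_after_x else x
                    if 2 <= cut <= len(seq):
                        positions.append(cut)
            return sorted(set(positions))
        for p in range(2, len(seq) + 1):
            if seq[p - 1] not in "ST":
                continue
            if self.requires_glycan_at_P1prime and p not in glycans:
                continue
            if self.p1_glycan_policy == "forbidden" and (p - 1) in glycans:
                continue
            if self.blocked_glycan is not None and self.blocked_glycan(glycans[p]):
                continue
            positions.append(p)
        return positions


def _contains_neuac(comp: GlycanComposition) -> bool:
    return comp.n_neuac > 0


SME = EnzymeRule("SmE")
IMPA = EnzymeRule("ImpA", p1_glycan_policy="forbidden")
OGPA = EnzymeRule("OgpA", blocked_glycan=_contains_neuac)
STCE = EnzymeRule("StcE", context_motif="T/S*_X_T/S")
ENZYMES: Mapping[str, EnzymeRule] = {r.name: r for r in (SME, IMPA, OGPA, STCE)}


# ----------------------------------------------------------------------
# Glycoproteins
# ----------------------------------------------------------------------

#: Default per-site glycan distribution: heterogeneous, core 1 dominated,
#: with sialylated, fucosylated and core 2 species in the mixture.
DEFAULT_GLYCAN_DISTRIBUTION: Mapping[str, float] = {
    "N1": 0.20,
    "N1A1": 0.05,
    "H1N1": 0.25,
    "H1N1F1": 0.05,
    "H1N1A1": 0.20,
    "H1N1A2": 0.10,
    "H2N2": 0.05,
    "H2N2A1": 0.05,
    "H2N2A2": 0.05,
}

_NON_ST = "ADEFGHIKLMNPQRVWY"  # Cys left out of random backbones


@dataclass(frozen=True)
class Glycoprotein:
    """A protein sequence with protein-coordinate glycan assignments."""

    protein_id: str
    sequence: str
    site_glycans: Mapping[int, GlycanComposition]

    def __post_init__(self) -> None:
        for pos, comp in self.site_glycans.items():
            if self.sequence[pos - 1] not in "ST":
                raise ValueError(f"glycan at {pos} not on S/T")
            if comp.is_zero:
                raise ValueError(f"zero composition at {pos}")
        object.__setattr__(self, "site_glycans", dict(self.site_glycans))

    @property
    def glycosites(self) -> tuple[int, ...]:
        return tuple(sorted(self.site_glycans))

    def adjacent_glycosite_pairs(self) -> int:
        sites = self.glycosites
        return sum(1 for a, b in zip(sites, sites[1:]) if b == a + 1)

    def adjacent_glycosite_fraction(self) -> float:
        """Fraction of glycosites whose +1 or -1 neighbour is a glycosite."""
        sites = set(self.glycosites)
        if not sites:
            return 0.0
        paired = sum(1 for s in sites if (s - 1) in sites or (s + 1) in sites)
        return paired / len(sites)

    def desialylated(self) -> "Glycoprotein":
        """Sialidase co-treatment: strip NeuAc from every glycan."""
        stripped = {
            pos: comp.strip_neuac()
            for pos, comp in self.site_glycans.items()
            if not comp.strip_neuac().is_zero
        }
        return Glycoprotein(self.protein_id, self.sequence, stripped)


def make_glycoprotein(
    seed: int,
    length: int = 240,
    mucin_region: tuple[int, int] | None = None,
    site_density: float = 0.6,
    glycan_distribution: Mapping[str, float] | None = None,
    st_fraction: float = 0.45,
    protein_id: str | None = None,
) -> Glycoprotein:
    """Generate a mucin glycoprotein with seeded site-specific glycans.

    The mucin region (default: middle half of the protein) is Ser/Thr
    enriched at ``st_fraction`` and each of its S/T residues is
    glycosylated with probability ``site_density``, drawing the glycan
    from ``glycan_distribution`` (composition string -> weight).
    """
    if not 0 < site_density <= 1:
        raise ValueError("site_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if mucin_region is None:
        mucin_region = (length // 4 + 1, 3 * length // 4)
    lo, hi = mucin_region
    dist = glycan_distribution or DEFAULT_GLYCAN_DISTRIBUTION
    comps = [parse_composition(s) for s in dist]
    weights = np.array(list(dist.values()), dtype=float)
    weights = weights / weights.sum()

    residues = []
    for pos in range(1, length + 1):
        if lo <= pos <= hi and rng.random() < st_fraction:
            residues.append("S" if rng.random() < 0.5 else "T")
        else:
            residues.append(_NON_ST[rng.integers(len(_NON_ST))])
    sequence = "".join(residues)

    site_glycans: dict[int, GlycanComposition] = {}
    for pos in range(lo, hi + 1):
        if sequence[pos - 1] in "ST" and rng.random() < site_density:
            site_glycans[pos] = comps[rng.choice(len(comps), p=weights)]
    return Glycoprotein(
        protein_id or f"SYN{seed:05d}", sequence, site_glycans
    )


# ----------------------------------------------------------------------
# Digestion
# ----------------------------------------------------------------------

def digest(
    glycoprotein: Glycoprotein,
    rule: EnzymeRule,
    missed_cleavages: int = 0,
    min_length: int = 1,
) -> list[Glycopeptide]:
    """Digest a glycoprotein under an enzyme rule.

    Products are emitted with 0..``missed_cleavages`` internal uncleaved
    sites; glycans are carried over into peptide coordinates.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = glycoprotein.sequence
    cuts = [1] + rule.cleavage_positions(glycoprotein) + [len(seq) + 1]
    cuts = sorted(set(cuts))
    products = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, stop = cuts[i], cuts[j]          # peptide covers start..stop-1
            pep = seq[start - 1 : stop - 1]
            if len(pep) < min_length:
                continue
            local = {
                pos - start + 1: comp
                for pos, comp in glycoprotein.site_glycans.items()
                if start <= pos < stop
            }
            products.append(
                Glycopeptide(
                    pep,
                    local,
                    protein_offset=start,
                    protein_id=glycoprotein.protein_id,
                )
            )
    return products


# ----------------------------------------------------------------------
# MS run generation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedGlycoform:
    glycopeptide: Glycopeptide
    abundance: float
    retention_time: float          # minutes, elution apex
    charge: int
    hcd_scan: str
    etd_scan: str | None


@dataclass
class SyntheticRun:
    """Spectra plus MS1 traces generated from planted glycoforms."""

    hcd_spectra: list[Spectrum]
    etd_spectra: dict[str, Spectrum]        # keyed by the HCD scan id
    ms1: Ms1Run
    truth: list[PlantedGlycoform] = field(default_factory=list)

    def etd_for(self, hcd: Spectrum) -> Spectrum | None:
        return self.etd_spectra.get(hcd.scan_id)


_ISOTOPE_ENVELOPE = np.array([1.0, 0.55, 0.2])
ELUTION_SIGMA_MIN = 0.2


def _oxonium_peaks(
    gp: Glycopeptide, rng: np.random.Generator
) -> tuple[list[float], list[float]]:
    total = gp.total_composition
    if total.is_zero:
        return [], []
    mz = [126.055, 138.055, 144.07, 168.065, 186.076, 204.086]
    # core 1 type fragmentation: 138 below 1.2x the 144 channel
    inten = [30.0, 85.0, 100.0, 25.0, 40.0, 100.0]
    if total.n_neuac > 0:
        mz += [274.092, 292.103]
        inten += [45.0, 60.0]
    if any(comp.n_hexnac >= 2 for comp in gp.site_glycans.values()):
        mz.append(OXONIUM_HEXNAC2)
        inten.append(20.0)
    return mz, inten


def make_run(
    glycoforms: Sequence[Glycopeptide | tuple[Glycopeptide, float]],
    seed: int = 0,
    dropout: float = 0.0,
    n_noise_peaks: int = 30,
    charges: Sequence[int] = (2, 3),
    charge_weights: Sequence[float] = (0.7, 0.3),
    rt_start: float = 5.0,
    rt_spacing: float = 1.0,
) -> SyntheticRun:
    """Simulate acquisition of a set of glycoforms.

    Each glycoform receives an HCD scan (glycan-free b/y with dropout, Y0,
    oxonium fingerprints scaled by glycan content, low-level noise) and,
    when the fingerprint trigger fires on that HCD scan, a paired EThcD
    scan of glycan-retaining c/z ions.  MS1 traces are Gaussian elution
    peaks on the isotope/charge channels the quantitation rules read, with
    total area equal to the planted abundance.
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    forms: list[tuple[Glycopeptide, float]] = [
        (f, 1000.0) if isinstance(f, Glycopeptide) else (f[0], float(f[1]))
        for f in glycoforms
    ]
    charge_weights = np.asarray(charge_weights, dtype=float)
    charge_weights = charge_weights / charge_weights.sum()

    hcd_spectra: list[Spectrum] = []
    etd_spectra: dict[str, Spectrum] = {}
    truth: list[PlantedGlycoform] = []
    channel_accum: dict[tuple[float, int], np.ndarray] = {}
    rt_max = rt_start + rt_spacing * len(forms) + 2.0
    rt_grid = np.arange(0.0, rt_max, 0.01)

    for i, (gp, abundance) in enumerate(forms):
        rt = rt_start + rt_spacing * i + rng.uniform(-0.05, 0.05)
        z0 = 2 if gp.neutral_mass < 2500 else 3
        scan_id = f"scan{i + 1:05d}"

        mz_list: list[float] = []
        int_list: list[float] = []
        frag_charge = max(1, z0 - 1)
        for ion in theoretical_fragments(gp, ("b", "y"), max_charge=frag_charge,
                                         precursor_charge=z0):
            if ion.series == "Y0":
                mz_list.append(ion.mz)
                int_list.append(50.0)
            elif rng.random() >= dropout:
                mz_list.append(ion.mz)
                int_list.append(float(rng.uniform(20.0, 90.0)))
        ox_mz, ox_int = _oxonium_peaks(gp, rng)
        mz_list += ox_mz
        int_list += ox_int
        noise_mz = rng.uniform(110.0, 1400.0, size=n_noise_peaks)
        noise_int = rng.uniform(0.5, 4.0, size=n_noise_peaks)
        mz_list += list(noise_mz)
        int_list += list(noise_int)

        hcd = Spectrum(
            scan_id=scan_id,
            activation=Activation.HCD,
            precursor_mz=gp.mz(z0),
            precursor_charge=z0,
            retention_time=rt,
            mz=np.array(mz_list),
            intensity=np.array(int_list),
        )
        hcd_spectra.append(hcd)

        etd_scan = None
        if should_trigger_etd(hcd)[0]:
            etd_scan = f"{scan_id}.etd"
            emz: list[float] = []
            eint: list[float] = []
            for ion in theoretical_fragments(gp, ("c", "z"), max_charge=frag_charge):
                if ion.series in ("c", "z") and rng.random() >= dropout:
                    emz.append(ion.mz)
                    eint.append(float(rng.uniform(30.0, 100.0)))
            emz.append(gp.mz(z0))
            eint.append(40.0)
            etd_spectra[scan_id] = Spectrum(
                scan_id=etd_scan,
                activation=Activation.ETHCD,
                precursor_mz=gp.mz(z0),
                precursor_charge=z0,
                retention_time=rt + 0.005,
                mz=np.array(emz),
                intensity=np.array(eint),
            )

        # MS1 channels: area is distributed over exactly the isotope and
        # charge channels the abundance rules integrate
        isotopes = isotopes_for_mass(gp.neutral_mass)
        iso_w = _ISOTOPE_ENVELOPE[: len(isotopes)]
        iso_w = iso_w / iso_w.sum()
        for z, wz in zip(charges, charge_weights):
            for k, wk in zip(isotopes, iso_w):
                mz = (gp.neutral_mass + k * ISOTOPE_SPACING + z * PROTON) / z
                area = abundance * wz * wk
                key = (round(mz, 6), z)
                profile = area * _gaussian(rt_grid, rt, ELUTION_SIGMA_MIN)
                if key in channel_accum:
                    channel_accum[key] += profile
                else:
                    channel_accum[key] = profile

        truth.append(PlantedGlycoform(gp, abundance, rt, z0, scan_id, etd_scan))

    ms1 = Ms1Run()
    for (mz, z), profile in channel_accum.items():
        ms1.add_channel(mz, z, ChromatographicTrace(rt_grid, profile))
    return SyntheticRun(hcd_spectra, etd_spectra, ms1, truth)


def _gaussian(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


def shuffled_copy(gp: Glycopeptide, rng: np.random.Generator) -> Glycopeptide:
    """A decoy with the same residue content but shuffled order.

    The glycan multiset is re-placed onto the S/T positions of the
    shuffled sequence, so the decoy has the same precursor mass as the
    target but different backbone fragments.
    """
    seq = list(gp.sequence)
    for _ in range(50):
        rng.shuffle(seq)
        if "".join(seq) != gp.sequence:
            break
    shuffled = "".join(seq)
    st_positions = [i + 1 for i, aa in enumerate(shuffled) if aa in "ST"]
    glycans = gp.glycan_multiset
    sites = dict(zip(st_positions, glycans))
    ox = frozenset()
    if gp.oxidized_met:
        met_positions = [i + 1 for i, aa in enumerate(shuffled) if aa == "M"]
        ox = frozenset(met_positions[: len(gp.oxidized_met)])
    return Glycopeptide(shuffled, sites, ox, gp.protein_offset, gp.protein_id)


# ----------------------------------------------------------------------
# Worm-like-chain trajectories
# ----------------------------------------------------------------------

def _kappa_from_mean_cos(c: float) -> float:
    """Stiffness kappa with Langevin mean cosine coth(k) - 1/k = c."""
    from scipy.optimize import brentq

    if not 0 < c < 1:
        raise ValueError("mean cosine must be in (0, 1)")

    def f(k: float) -> float:
        return (1.0 / np.tanh(k) - 1.0 / k) - c

    return brentq(f, 1e-8, 1e8, maxiter=200)


def _sample_cos_theta(kappa: float, rng: np.random.Generator, size) -> np.ndarray:
    """Inverse-CDF draw from p(cos) ∝ exp(kappa*cos) on [-1, 1]."""
    u = rng.random(size)
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def make_wlc_trajectory(
    seed: int,
    n_monomers: int = 200,
    lb: float = 3.8,
    lp: float = 100.0,
    n_frames: int = 2000,
    replica_id: str = "rep1",
) -> PolymerTrajectory:
    """Worm-like-chain ensemble with known persistence length.

    Each frame is an independent chain whose successive bond deflection
    has mean cosine ``exp(-lb/lp)``, so the planted bond autocorrelation
    is ``C(n) = exp(-n*lb/lp)``.  Monomers are single pseudo-atoms named
    CA with resids 1..n.
    """
    if lb <= 0 or lp <= 0:
        raise ValueError("lb and lp must be positive")
    rng = np.random.default_rng(seed)
    kappa = _kappa_from_mean_cos(float(np.exp(-lb / lp)))
    F, N = n_frames, n_monomers
    B = N - 1

    # initial bond directions: uniform on the sphere
    v = rng.normal(size=(F, 3))
    d = v / np.linalg.norm(v, axis=1, keepdims=True)
    directions = np.empty((F, B, 3))
    directions[:, 0, :] = d
    for b in range(1, B):
        cos_t = _sample_cos_theta(kappa, rng, F)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        phi = rng.uniform(0.0, 2.0 * np.pi, F)
        helper = np.where(
            (np.abs(d[:, 2]) < 0.9)[:, None], [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]]
        )
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d, e1)
        d = (
            cos_t[:, None] * d
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        directions[:, b, :] = d

    coords = np.zeros((F, N, 3))
    coords[:, 1:, :] = np.cumsum(directions * lb, axis=1)
    return PolymerTrajectory(
        coords,
        resids=np.arange(1, N + 1),
        atom_names=["CA"] * N,
        masses=np.full(N, 12.011),
        replica_id=replica_id,
    )


# ----------------------------------------------------------------------
# SPR sensorgrams
# ----------------------------------------------------------------------

def make_spr_sensorgram(
    seed: int,
    K: float,
    Y0: float,
    NS: float,
    times: np.ndarray | None = None,
    sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-phase exponential dissociation decay with Gaussian noise.

    Returns (times in s re-zeroed to dissociation start, response in RU).
    The default time base covers a 125 s dissociation window sampled at
    2.5 Hz, the nominal collection rate of a Biacore 3000.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(0.0, 125.0, 0.4)
    times = np.asarray(times, dtype=float)
    y = (Y0 - NS) * np.exp(-K * times) + NS
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=times.shape)
    return times, y


# ----------------------------------------------------------------------
# Run directory writer (used by the CLI `simulate` command)
# ----------------------------------------------------------------------

def write_run(
    outdir: str | Path,
    glycoprotein: Glycoprotein,
    run: SyntheticRun,
) -> dict:
    """Write FASTA, MGF, MS1 trace CSV and a truth/manifest JSON."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .spectra import write_mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "proteins.fasta"
    SeqIO.write(
        [SeqRecord(Seq(glycoprotein.sequence), id=glycoprotein.protein_id, description="")],
        str(fasta),
        "fasta",
    )
    mgf = outdir / "spectra.mgf"
    all_spectra = list(run.hcd_spectra) + list(run.etd_spectra.values())
    write_mgf(all_spectra, mgf)
    ms1_csv = outdir / "ms1_traces.csv"
    run.ms1.to_csv(ms1_csv)
    truth = {
        "protein_id": glycoprotein.protein_id,
        "site_glycans": {
            str(pos): comp.to_string() for pos, comp in sorted(glycoprotein.site_glycans.items())
        },
        "glycoforms": [
            {
                "peptide": p.glycopeptide.sequence,
                "protein_offset": p.glycopeptide.protein_offset,
                "site_glycans": {
                    str(pos): c.to_string()
                    for pos, c in sorted(p.glycopeptide.site_glycans.items())
                },
                "abundance": p.abundance,
                "retention_time": p.retention_time,
                "charge": p.charge,
                "hcd_scan": p.hcd_scan,
                "etd_scan": p.etd_scan,
            }
            for p in run.truth
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    manifest = {
        "fasta": fasta.name,
        "mgf": mgf.name,
        "ms1_traces": ms1_csv.name,
        "truth": "truth.json",
        "n_hcd": len(run.hcd_spectra),
        "n_etd": len(run.etd_spectra),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
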