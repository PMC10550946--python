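"""Spectrum model, theoretical fragment generation, peak matching and the
oxonium-fingerprint ETD trigger.

Fragmentation conventions: HCD b/y ions are generated glycan-free (mucin
O-glycans are labile under collisional activation), electron-based c/z
ions retain the glycans N-terminal (c) or C-terminal (z) of each site,
and Y0 is the intact peptide stripped of all glycans.  z ions are
modelled as z-dot radicals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .glyco import GlycanComposition
from .peptide import NH2, NH3, PROTON, WATER, CARBAMIDOMETHYL, MET_OXIDATION, Glycopeptide, residue_mass

__all__ = [
    "Activation",
    "Spectrum",
    "TheoreticalIon",
    "FragmentMatch",
    "FINGERPRINT_IONS",
    "OXONIUM_HEXNAC",
    "OXONIUM_HEXNAC2",
    "theoretical_fragments",
    "match_peaks",
    "should_trigger_etd",
    "fingerprint_ratio",
    "read_mgf",
    "write_mgf",
    "read_peaklist_tsv",
    "write_peaklist_tsv",
]

#: HexNAc/NeuAc fingerprint oxonium ions (m/z) used by the acquisition
#: method's product-dependent ETD trigger, as configured on the instrument.
FINGERPRINT_IONS: tuple[float, ...] = (
    126.055, 138.055, 144.07, 168.065, 186.076, 204.086, 274.092, 292.103,
)
#: HexNAc oxonium used for candidate-scan extraction.
OXONIUM_HEXNAC = 204.0867
#: HexNAc2 oxonium; its presence vetoes splitting an N2 composition.
OXONIUM_HEXNAC2 = 407.166

TRIGGER_MZ_TOL = 0.1          # ± m/z window for fingerprint ions
TRIGGER_MIN_REL = 0.05        # >5 % relative intensity
TRIGGER_MIN_COUNT = 3         # 3 of 8 fingerprints
TRIGGER_PRECURSOR_RANGE = (300.0, 1500.0)
TRIGGER_CHARGES = range(2, 7)


class Activation(enum.Enum):
    HCD = "HCD"
    ETD = "ETD"
    ETHCD = "EThcD"


@dataclass
class Spectrum:
    """A centroided MS2 spectrum with precursor metadata.

    Peaks are kept sorted by m/z; intensities are non-negative.
    """

    scan_id: str
    activation: Activation
    precursor_mz: float
    precursor_charge: int
    retention_time: float          # minutes
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    @property
    def precursor_neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.precursor_charge

    def intensity_near(self, mz: float, tol_mz: float) -> float:
        """Summed intensity of all peaks within ``±tol_mz`` of ``mz``."""
        lo, hi = np.searchsorted(self.mz, (mz - tol_mz, mz + tol_mz + 1e-12))
        return float(self.intensity[lo:hi].sum())

    def has_peak_near(self, mz: float, tol_mz: float, min_intensity: float = 0.0) -> bool:
        lo, hi = np.searchsorted(self.mz, (mz - tol_mz, mz + tol_mz + 1e-12))
        return bool(hi > lo and self.intensity[lo:hi].max() > min_intensity)


@dataclass(frozen=True)
class TheoreticalIon:
    series: str                    # b, y, c, z, Y0
    index: int                     # fragment length; 0 for Y0
    charge: int
    mz: float
    glycan_retained: GlycanComposition = GlycanComposition()


@dataclass(frozen=True)
class FragmentMatch:
    ion: TheoreticalIon
    observed_mz: float
    observed_intensity: float
    error_ppm: float
    ambiguous: bool = False        # same peak explains several theoreticals

    @property
    def series(self) -> str:
        return self.ion.series

    @property
    def index(self) -> int:
        return self.ion.index


def _prefix_masses(gp: Glycopeptide) -> np.ndarray:
    """Cumulative modified residue masses; entry i covers residues 1..i."""
    masses = np.zeros(len(gp.sequence))
    for i, aa in enumerate(gp.sequence, start=1):
        m = residue_mass(aa)
        if aa == "C":
            m += CARBAMIDOMETHYL
        if i in gp.oxidized_met:
            m += MET_OXIDATION
        masses[i - 1] = m
    return np.cumsum(masses)


def _retained(gp: Glycopeptide, positions: Iterable[int]) -> GlycanComposition:
    total = GlycanComposition()
    for pos in positions:
        comp = gp.site_glycans.get(pos)
        if comp is not None:
            total = total + comp
    return total


def theoretical_fragments(
    gp: Glycopeptide,
    series_set: Sequence[str] = ("b", "y", "c", "z"),
    max_charge: int = 1,
    include_glycosylated_by: bool = False,
    precursor_charge: int | None = None,
) -> list[TheoreticalIon]:
    """Theoretical backbone fragments plus Y0 for a glycopeptide.

    b/y are glycan-free by default (optionally also glycan-retaining);
    c/z retain the glycans on their residues; z ions are z-dot.  Y0 is
    generated at charges 1..(``precursor_charge`` or ``max_charge``).
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(gp.sequence)
    prefix = _prefix_masses(gp)
    total = prefix[-1]
    ions: list[TheoreticalIon] = []

    def add(series: str, index: int, neutral: float, retained: GlycanComposition) -> None:
        for z in range(1, max_charge + 1):
            ions.append(TheoreticalIon(series, index, z, (neutral + z * PROTON) / z, retained))

    for i in range(1, n):
        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[i - 1] + WATER
        n_term_glyc = _retained(gp, range(1, i + 1))
        c_term_glyc = _retained(gp, range(i + 1, n + 1))
        if "b" in series_set:
            add("b", i, b_neutral, GlycanComposition())
            if include_glycosylated_by and not n_term_glyc.is_zero:
                add("b", i, b_neutral + n_term_glyc.mass, n_term_glyc)
        if "y" in series_set:
            add("y", n - i, y_neutral, GlycanComposition())
            if include_glycosylated_by and not c_term_glyc.is_zero:
                add("y", n - i, y_neutral + c_term_glyc.mass, c_term_glyc)
        if "c" in series_set:
            add("c", i, b_neutral + NH3 + n_term_glyc.mass, n_term_glyc)
        if "z" in series_set:
            add("z", n - i, y_neutral - NH2 + c_term_glyc.mass, c_term_glyc)

    y0_charges = precursor_charge or max_charge
    for z in range(1, y0_charges + 1):
        ions.append(
            TheoreticalIon("Y0", 0, z, (gp.naked_mass + z * PROTON) / z, GlycanComposition())
        )
    return ions


def match_peaks(
    spec: Spectrum,
    theoretical: Sequence[TheoreticalIon],
    tol_ppm: float = 20.0,
) -> list[FragmentMatch]:
    """Greedy nearest-peak assignment of theoretical ions within a ppm window.

    Each theoretical ion takes its nearest observed peak within tolerance.
    A peak claimed by several theoreticals yields matches flagged ambiguous
    (the "?" semantics of manual annotation).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if spec.n_peaks == 0:
        return []
    matches: list[FragmentMatch] = []
    peak_use: dict[int, list[int]] = {}
    for ion in theoretical:
        tol = ion.mz * tol_ppm * 1e-6
        lo, hi = np.searchsorted(spec.mz, (ion.mz - tol, ion.mz + tol))
        if hi <= lo:
            continue
        window = spec.mz[lo:hi]
        k = lo + int(np.argmin(np.abs(window - ion.mz)))
        obs_mz = float(spec.mz[k])
        err = (obs_mz - ion.mz) / ion.mz * 1e6
        peak_use.setdefault(k, []).append(len(matches))
        matches.append(FragmentMatch(ion, obs_mz, float(spec.intensity[k]), err))
    shared = {i for idxs in peak_use.values() if len(idxs) > 1 for i in idxs}
    return [
        FragmentMatch(m.ion, m.observed_mz, m.observed_intensity, m.error_ppm, ambiguous=(i in shared))
        for i, m in enumerate(matches)
    ]


def should_trigger_etd(spec: Spectrum) -> tuple[bool, list[float]]:
    """Product-dependent ETD trigger on an HCD scan.

    Fires iff the precursor lies in 300–1500 m/z with charge 2–6 and at
    least 3 of the 8 HexNAc/NeuAc fingerprint ions have a peak within
    ±0.1 m/z at >5 % of the base peak.  Returns (decision, ions found).
    """
    found: list[float] = []
    if spec.n_peaks == 0:
        return False, found
    floor = TRIGGER_MIN_REL * spec.base_peak_intensity
    for fp in FINGERPRINT_IONS:
        if spec.has_peak_near(fp, TRIGGER_MZ_TOL, min_intensity=floor):
            found.append(fp)
    lo, hi = TRIGGER_PRECURSOR_RANGE
    ok = (
        lo <= spec.precursor_mz <= hi
        and spec.precursor_charge in TRIGGER_CHARGES
        and len(found) >= TRIGGER_MIN_COUNT
    )
    return ok, found


def fingerprint_ratio(spec: Spectrum, tol_mz: float = TRIGGER_MZ_TOL) -> float:
    """Intensity ratio of the 138.055 and 144.07 oxonium channels.

    Returns ``inf`` when the 144 channel is empty but 138 is present and
    ``nan`` when both are empty.  A ratio strictly under 1.2 indicates
    core 1 type glycans.
    """
    i138 = spec.intensity_near(138.055, tol_mz)
    i144 = spec.intensity_near(144.07, tol_mz)
    if i144 == 0.0:
        return float("inf") if i138 > 0 else float("nan")
    return i138 / i144


# ----------------------------------------------------------------------
# I/O: MGF and a TSV peak-list dialect
# ----------------------------------------------------------------------

def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    from pyteomics import mgf as _mgf

    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.scan_id,
                    "pepmass": (s.precursor_mz,),
                    "charge": s.precursor_charge,
                    "rtinseconds": s.retention_time * 60.0,
                    "activation": s.activation.value,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    from pyteomics import mgf as _mgf

    out = []
    with _mgf.read(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge", [1])
            charge = int(charge[0]) if isinstance(charge, (list, tuple)) else int(charge)
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            act = str(params.get("activation", "HCD"))
            out.append(
                Spectrum(
                    scan_id=str(params.get("title", "")),
                    activation=Activation(act),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    retention_time=rt,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return out


def write_peaklist_tsv(spectra: Iterable[Spectrum], path) -> None:
    """Long-format TSV: scan_id, activation, precursor_mz, precursor_charge,
    retention_time_min, mz, intensity (one row per peak)."""
    import pandas as pd

    rows = []
    for s in spectra:
        for mz, inten in zip(s.mz, s.intensity):
            rows.append(
                (s.scan_id, s.activation.value, s.precursor_mz, s.precursor_charge,
                 s.retention_time, mz, inten)
            )
    pd.DataFrame(
        rows,
        columns=["scan_id", "activation", "precursor_mz", "precursor_charge",
                 "retention_time_min", "mz", "intensity"],
    ).to_csv(path, sep="\t", index=False)


def read_peaklist_tsv(path) -> list[Spectrum]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for scan_id, grp in df.groupby("scan_id", sort=False):
        first = grp.iloc[0]
        out.append(
            Spectrum(
                scan_id=str(scan_id),
                activation=Activation(first["activation"]),
                precursor_mz=float(first["precursor_mz"]),
                precursor_charge=int(first["precursor_charge"]),
                retention_time=float(first["retention_time_min"]),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out
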