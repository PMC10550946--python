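import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mucintools.glyco import parse_composition
from mucintools.peptide import Glycopeptide
from mucintools.spectra import Activation, Spectrum, theoretical_fragments


def spectrum_from_ions(
    ions,
    precursor_mz,
    precursor_charge,
    activation=Activation.HCD,
    intensity=100.0,
    extra_peaks=(),
    scan_id="scan1",
    rt=10.0,
):
    """Build a Spectrum containing exactly the given theoretical ions."""
    mz = [ion.mz for ion in ions] + [p[0] for p in extra_peaks]
    inten = [intensity] * len(ions) + [p[1] for p in extra_peaks]
    return Spectrum(
        scan_id=scan_id,
        activation=activation,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        retention_time=rt,
        mz=np.array(mz),
        intensity=np.array(inten),
    )


@pytest.fixture
def tn():
    return parse_composition("N1")


@pytest.fixture
def core1():
    return parse_composition("H1N1")


@pytest.fixture
def simple_glycopeptide(tn):
    """AVFTTA with Tn on both Thr, the worked peptide used throughout."""
    return Glycopeptide("AVFTTA", {4: tn, 5: tn})


def full_hcd_spectrum(gp: Glycopeptide, charge: int = 2, oxonium=True):
    """HCD spectrum with all glycan-free b/y, Y0 and (optionally) oxonium ions."""
    ions = theoretical_fragments(
        gp, ("b", "y"), max_charge=max(1, charge - 1), precursor_charge=charge
    )
    extra = []
    if oxonium and gp.site_glycans:
        extra = [(138.055, 80.0), (144.07, 100.0), (204.086, 100.0), (126.055, 30.0)]
    return spectrum_from_ions(ions, gp.mz(charge), charge, extra_peaks=extra)


def full_etd_spectrum(gp: Glycopeptide, charge: int = 2):
    """EThcD spectrum with all glycan-retaining c/z ions."""
    ions = [
        t
        for t in theoretical_fragments(gp, ("c", "z"), max_charge=max(1, charge - 1))
        if t.series in ("c", "z")
    ]
    return spectrum_from_ions(ions, gp.mz(charge), charge, activation=Activation.ETHCD)
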