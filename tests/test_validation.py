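"""The manual-validation rulebook: naked-peptide and coverage rules,
c/z localization, residual matching, spectral transfer and the combined
decision."""

import itertools

import numpy as np
import pytest

from mucintools.glyco import GlycanComposition, parse_composition
from mucintools.peptide import MET_OX_SIDECHAIN_LOSS, PROTON, Glycopeptide
from mucintools.spectra import (
    Activation,
    Spectrum,
    match_peaks,
    theoretical_fragments,
)
from mucintools.validation import (
    SiteStatus,
    Status,
    ValidationConfig,
    check_backbone_coverage,
    check_naked_peptide,
    find_candidate_scans,
    localize_glycans,
    residual_match,
    transfer_identification,
    validate,
)

from conftest import full_etd_spectrum, full_hcd_spectrum, spectrum_from_ions


def peak_spectrum(peaks, precursor_mz, charge, activation=Activation.HCD):
    return Spectrum(
        "s", activation, precursor_mz, charge, 10.0,
        np.array([p[0] for p in peaks]), np.array([p[1] for p in peaks]),
    )


class TestNakedPeptide:
    def test_y0_present_passes(self, simple_glycopeptide):
        gp = simple_glycopeptide
        spec = peak_spectrum([(gp.naked_mass + PROTON, 50.0)], gp.mz(2), 2)
        assert check_naked_peptide(gp, spec).passed

    def test_met_ox_side_chain_loss_counts_as_naked(self):
        gp = Glycopeptide("AMFTTA", {4: parse_composition("N1")}, oxidized_met={2})
        loss_mz = gp.naked_mass - MET_OX_SIDECHAIN_LOSS + PROTON
        spec = peak_spectrum([(loss_mz, 50.0)], gp.mz(2), 2)
        result = check_naked_peptide(gp, spec)
        assert result.passed and "CH4SO" in result.detail

    def test_loss_peak_without_oxidation_fails(self, simple_glycopeptide):
        gp = simple_glycopeptide
        loss_mz = gp.naked_mass - MET_OX_SIDECHAIN_LOSS + PROTON
        spec = peak_spectrum([(loss_mz, 50.0)], gp.mz(2), 2)
        assert not check_naked_peptide(gp, spec).passed

    def test_no_y0_fails(self, simple_glycopeptide):
        gp = simple_glycopeptide
        spec = peak_spectrum([(400.0, 50.0)], gp.mz(2), 2)
        assert not check_naked_peptide(gp, spec).passed


def matches_for(gp, series_indices, charge=2):
    """Matches containing exactly the requested glycan-free (series, index) ions."""
    theo = theoretical_fragments(gp, ("b", "y"), max_charge=1)
    wanted = [
        t for t in theo
        if (t.series, t.index) in series_indices and t.glycan_retained.is_zero
    ]
    spec = spectrum_from_ions(wanted, gp.mz(charge), charge)
    return match_peaks(spec, wanted, 20.0)


class TestBackboneCoverage:
    def test_full_coverage_short_peptide(self):
        gp = Glycopeptide("AVFTTA")
        matches = matches_for(gp, {("b", i) for i in range(1, 6)})
        result, frac = check_backbone_coverage(gp, matches)
        assert result.passed and frac == 1.0

    def test_sparse_coverage_fails_short_peptide(self):
        gp = Glycopeptide("AVFTTA")
        matches = matches_for(gp, {("b", 1), ("b", 2)})
        result, frac = check_backbone_coverage(gp, matches)
        assert not result.passed and frac == pytest.approx(0.4)

    def test_b_n_minus_1_satisfies_final_bond_with_cterm_pro(self):
        gp = Glycopeptide("AVFTTP")
        matches = matches_for(gp, {("b", 5)})
        _, frac = check_backbone_coverage(gp, matches)
        # bond 5 (the C-terminal bond) is covered by b5 alone
        assert frac == pytest.approx(0.2)
        covered = {m.index for m in matches if m.series == "b"}
        assert 5 in covered

    def test_long_peptide_requires_pro_asp_bonds(self):
        seq = "AVFTTAGLKAVFTTAGLKAV"          # 20-mer
        seq = seq[:7] + "P" + seq[8:]          # Pro at position 8
        gp = Glycopeptide(seq)
        # everything except the bond N-terminal to Pro (bond 7)
        idx = {("b", i) for i in range(1, 20) if i != 7}
        result, _ = check_backbone_coverage(gp, matches_for(gp, idx))
        assert not result.passed and "7" in result.detail

    def test_long_peptide_passes_when_anchor_bonds_covered(self):
        seq = "AVFTTAGLKAVFTTAGLKAV"
        seq = seq[:7] + "P" + seq[8:]
        gp = Glycopeptide(seq)
        result, _ = check_backbone_coverage(gp, matches_for(gp, {("b", 7)}))
        assert result.passed

    def test_y_ions_cover_bonds_from_cterm(self):
        gp = Glycopeptide("AVFTTA")
        matches = matches_for(gp, {("y", i) for i in range(1, 6)})
        result, frac = check_backbone_coverage(gp, matches)
        assert result.passed and frac == 1.0


def localization_oracle(gp, etd, tol_ppm=20.0):
    """Brute-force oracle: enumerate arrangements, build implied c/z sets,
    collect evidence, intersect.  Independent of the engine's code path."""
    sites = gp.candidate_sites
    glycans = list(gp.glycan_multiset)
    arrangements = []
    for combo in set(itertools.permutations(glycans + [None] * (len(sites) - len(glycans)))):
        arrangements.append({s: g for s, g in zip(sites, combo) if g is not None})
    max_charge = max(1, etd.precursor_charge - 1)
    implied, evidence = [], set()
    for arr in arrangements:
        gp_arr = gp.with_sites(arr)
        theo = [t for t in theoretical_fragments(gp_arr, ("c", "z"), max_charge)
                if t.series in ("c", "z")]
        imp = {(t.series, t.index): t.glycan_retained for t in theo}
        implied.append(imp)
        for t in theo:
            tol = t.mz * tol_ppm * 1e-6
            lo, hi = np.searchsorted(etd.mz, (t.mz - tol, t.mz + tol))
            if hi > lo:
                evidence.add((t.series, t.index, t.glycan_retained))
    naked = [t for t in theoretical_fragments(gp.with_sites({}), ("c", "z"), max_charge)
             if t.series in ("c", "z")]
    for t in naked:
        tol = t.mz * tol_ppm * 1e-6
        lo, hi = np.searchsorted(etd.mz, (t.mz - tol, t.mz + tol))
        if hi > lo:
            evidence.add((t.series, t.index, t.glycan_retained))
    consistent = [a for a, imp in zip(arrangements, implied)
                  if all(imp[(s, i)] == g for s, i, g in evidence)]
    if not consistent:
        return {s: SiteStatus.CONTRADICTED for s in sites}
    out = {}
    for s in sites:
        vals = {a.get(s) for a in consistent}
        if len(vals) == 1 and vals != {None}:
            out[s] = SiteStatus.LOCALIZED
        else:
            out[s] = SiteStatus.UNLOCALIZED
    return out


class TestLocalization:
    def test_bracketing_c_ions_localize(self, tn):
        gp = Glycopeptide("ATSA", {2: tn})
        theo = theoretical_fragments(gp, ("c",), 1)
        c23 = [t for t in theo if t.series == "c" and t.index in (2, 3)]
        etd = spectrum_from_ions(c23, gp.mz(2), 2, activation=Activation.ETHCD)
        status, assigned = localize_glycans(gp, etd)
        assert status[2] is SiteStatus.LOCALIZED
        assert assigned[2] == tn
        assert status[3] is SiteStatus.UNLOCALIZED

    def test_no_bracketing_ion_leaves_both_unlocalized(self, tn):
        gp = Glycopeptide("ATSA", {2: tn})
        theo = [t for t in theoretical_fragments(gp, ("c", "z"), 1)
                if (t.series, t.index) in {("c", 1), ("z", 1)}]
        etd = spectrum_from_ions(theo, gp.mz(2), 2, activation=Activation.ETHCD)
        status, _ = localize_glycans(gp, etd)
        assert status[2] is SiteStatus.UNLOCALIZED
        assert status[3] is SiteStatus.UNLOCALIZED

    def test_conflicting_evidence_contradicts(self, tn):
        # both sites carry a glycan, so every arrangement implies c2
        # retains one; a matched glycan-free c2 contradicts all of them
        gp = Glycopeptide("ATSA", {2: tn, 3: tn})
        naked = Glycopeptide("ATSA")
        theo = [t for t in theoretical_fragments(naked, ("c",), 1) if t.index == 2]
        etd = spectrum_from_ions(theo, gp.mz(2), 2, activation=Activation.ETHCD)
        status, _ = localize_glycans(gp, etd)
        assert all(st is SiteStatus.CONTRADICTED for st in status.values())

    def test_no_etd_means_unlocalized(self, simple_glycopeptide):
        status, assigned = localize_glycans(simple_glycopeptide, None)
        assert all(st is SiteStatus.UNLOCALIZED for st in status.values())
        assert assigned == {}

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        db = [parse_composition(s) for s in ("N1", "H1N1", "H1N1A1")]
        seq = "".join(rng.choice(list("ASTGLPTS")) for _ in range(rng.integers(5, 9)))
        sites = [i + 1 for i, aa in enumerate(seq) if aa in "ST"]
        if not sites:
            seq += "T"
            sites = [len(seq)]
        k = int(rng.integers(1, min(3, len(sites)) + 1))
        chosen = sorted(rng.choice(sites, size=k, replace=False))
        gp = Glycopeptide(seq, {int(s): db[rng.integers(len(db))] for s in chosen})
        # a partial ETD spectrum: random half of the true c/z ions
        theo = [t for t in theoretical_fragments(gp, ("c", "z"), 1) if t.series in ("c", "z")]
        keep = [t for t in theo if rng.random() < 0.5]
        etd = spectrum_from_ions(keep, gp.mz(2), 2, activation=Activation.ETHCD)
        status, _ = localize_glycans(gp, etd)
        assert status == localization_oracle(gp, etd)


class TestCandidateScans:
    def test_scans_with_204_returned(self, simple_glycopeptide):
        gp = simple_glycopeptide
        with_204 = peak_spectrum([(204.0867, 50.0), (500.0, 100.0)], gp.mz(2), 2)
        without = peak_spectrum([(500.0, 100.0)], gp.mz(2), 2)
        out = find_candidate_scans([with_204, without])
        assert out == [with_204]

    def test_trigger_branch_includes_weak_204(self):
        # 204 below the 5% floor, but three other fingerprints fire the trigger
        peaks = [(500.0, 100.0), (204.0867, 1.0), (126.055, 10.0),
                 (138.055, 10.0), (292.103, 10.0)]
        spec = peak_spectrum(peaks, 800.0, 2)
        assert find_candidate_scans([spec]) == [spec]

    def test_empty_run(self):
        assert find_candidate_scans([]) == []


class TestResidualMatch:
    def test_two_hexnac_residual(self):
        gp = Glycopeptide("AVFTTA", {4: parse_composition("N1"), 5: parse_composition("N1")})
        scan = peak_spectrum([(500.0, 1.0)], gp.mz(2), 2)
        assert residual_match(scan, "AVFTTA") == [parse_composition("N2")]

    def test_negative_residual_is_empty(self):
        naked = Glycopeptide("AVFTTAK")
        scan = peak_spectrum([(500.0, 1.0)], (naked.naked_mass - 5.0 + 2 * PROTON) / 2, 2)
        assert residual_match(scan, "AVFTTAK") == []

    def test_core1_residual(self):
        gp = Glycopeptide("AVFTTA", {4: parse_composition("H1N1")})
        scan = peak_spectrum([(500.0, 1.0)], gp.mz(2), 2)
        assert residual_match(scan, "AVFTTA") == [parse_composition("H1N1")]


class TestTransfer:
    def test_scaled_spectrum_has_unit_similarity(self, simple_glycopeptide):
        gp = simple_glycopeptide
        strong = full_hcd_spectrum(gp)
        weak = Spectrum("w", Activation.HCD, strong.precursor_mz, 2, 11.0,
                        strong.mz.copy(), strong.intensity * 0.1)
        ok, sim = transfer_identification((gp, strong), weak)
        assert ok and sim == pytest.approx(1.0)

    def test_random_peaks_rejected(self, simple_glycopeptide):
        gp = simple_glycopeptide
        strong = full_hcd_spectrum(gp)
        rng = np.random.default_rng(11)
        weak = Spectrum("w", Activation.HCD, strong.precursor_mz, 2, 11.0,
                        np.sort(rng.uniform(100, 1500, 60)), rng.uniform(1, 100, 60))
        ok, sim = transfer_identification((gp, strong), weak)
        assert not ok and sim < 0.3

    def test_half_channels_computed_on_shared_support(self, simple_glycopeptide):
        gp = simple_glycopeptide
        strong = full_hcd_spectrum(gp)
        half = strong.mz.size // 2
        weak = Spectrum("w", Activation.HCD, strong.precursor_mz, 2, 11.0,
                        strong.mz[:half], strong.intensity[:half])
        ok, sim = transfer_identification((gp, strong), weak)
        assert 0.0 < sim < 1.0


class TestValidateDecision:
    def test_all_rules_pass_with_localization(self, simple_glycopeptide):
        gp = simple_glycopeptide
        decision = validate(gp, full_hcd_spectrum(gp), full_etd_spectrum(gp))
        assert decision.status is Status.ACCEPT
        assert decision.site_status[4] is SiteStatus.LOCALIZED
        assert decision.site_status[5] is SiteStatus.LOCALIZED

    def test_naked_failure_rejects_despite_coverage(self, simple_glycopeptide):
        gp = simple_glycopeptide
        theo = [t for t in theoretical_fragments(gp, ("b", "y"), 1) if t.series in "by"]
        hcd = spectrum_from_ions(theo, gp.mz(2), 2)   # no Y0 peak
        decision = validate(gp, hcd, None)
        assert decision.status is Status.REJECT
        assert not [r for r in decision.reasons if r.rule == "naked_peptide"][0].passed

    def test_unlocalized_n2_decomposes_to_two_tn(self, simple_glycopeptide):
        gp = simple_glycopeptide  # N1 on each of two T's; total N2
        hcd = full_hcd_spectrum(gp)   # oxonium 138/144 = 0.8, no 407
        decision = validate(gp, hcd, None)
        assert decision.status is Status.ACCEPT
        assert decision.assigned_site_glycans == {
            4: parse_composition("N1"), 5: parse_composition("N1")
        }
        rules = {r.rule for r in decision.reasons}
        assert "multisite_decomposition" in rules

    def test_407_blocks_decomposition(self, simple_glycopeptide):
        gp = simple_glycopeptide
        hcd = full_hcd_spectrum(gp)
        hcd = Spectrum(hcd.scan_id, hcd.activation, hcd.precursor_mz, 2, hcd.retention_time,
                       np.append(hcd.mz, 407.166), np.append(hcd.intensity, 20.0))
        decision = validate(gp, hcd, None)
        assert decision.status is Status.ACCEPT
        assert decision.assigned_site_glycans == {}

    def test_decisions_are_deterministic(self, simple_glycopeptide):
        gp = simple_glycopeptide
        hcd, etd = full_hcd_spectrum(gp), full_etd_spectrum(gp)
        d1, d2 = validate(gp, hcd, etd), validate(gp, hcd, etd)
        assert d1.status == d2.status
        assert d1.site_status == d2.site_status
        assert [(r.rule, r.passed) for r in d1.reasons] == [(r.rule, r.passed) for r in d2.reasons]
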