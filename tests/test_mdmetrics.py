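"""Polymer metrics: end-to-end distance, bending angle, bond
autocorrelation / persistence length and height-per-glycan."""

import numpy as np
import pytest

from mucintools.mdmetrics import (
    MucinSelection,
    PolymerTrajectory,
    bending_angle_series,
    bond_autocorrelation,
    end_to_end_series,
    height_per_glycan,
    persistence_length,
)
from mucintools.synthetic import make_wlc_trajectory


def straight_chain(n_residues=71, spacing=3.5, n_frames=1):
    coords = np.zeros((n_frames, n_residues, 3))
    coords[:, :, 0] = np.arange(n_residues) * spacing
    return PolymerTrajectory(
        coords, np.arange(1, n_residues + 1), ["CA"] * n_residues,
        np.full(n_residues, 12.0),
    )


def anchored_trajectory(points):
    """One frame with one CA atom per residue at the given coordinates."""
    coords = np.asarray(points, dtype=float)[None, :, :]
    n = coords.shape[1]
    return PolymerTrajectory(coords, np.arange(1, n + 1), ["CA"] * n, np.ones(n))


def random_rigid_transform(rng):
    q = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(q)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-50, 50, 3)
    return Q, t


class TestEndToEnd:
    def test_collinear_chain_value(self):
        traj = straight_chain(71, 3.5)
        sel = MucinSelection(1, 71, n_glycans=14, n_mucin_residues=71)
        e2e = end_to_end_series(traj, sel)
        assert e2e[0] == pytest.approx(70 * 3.5 / 71)

    def test_identical_anchors_give_zero(self):
        traj = anchored_trajectory([[0, 0, 0], [1, 0, 0], [0, 0, 0]])
        sel = MucinSelection(1, 3, n_glycans=1, n_mucin_residues=3)
        assert end_to_end_series(traj, sel)[0] == 0.0

    def test_missing_residue_error_names_it(self):
        traj = straight_chain(5)
        sel = MucinSelection(1, 5, n_glycans=1, n_mucin_residues=5, e2e_anchors=(1, 99))
        with pytest.raises(ValueError, match="99"):
            end_to_end_series(traj, sel)


class TestBendingAngle:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([[0, 0, 0], [1, 0, 0], [2, 0, 0]], 180.0),
            ([[0, 1, 0], [0, 0, 0], [1, 0, 0]], 90.0),
            ([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], 60.0),
        ],
    )
    def test_reference_geometries(self, points, expected):
        traj = anchored_trajectory(points)
        sel = MucinSelection(1, 3, n_glycans=1, n_mucin_residues=3, bend_anchors=(1, 2, 3))
        assert bending_angle_series(traj, sel)[0] == pytest.approx(expected, abs=1e-9)

    def test_degenerate_vector_is_nan(self):
        traj = anchored_trajectory([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        sel = MucinSelection(1, 3, n_glycans=1, n_mucin_residues=3, bend_anchors=(1, 2, 3))
        assert np.isnan(bending_angle_series(traj, sel)[0])


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", range(3))
    def test_metrics_invariant_under_rotation_translation(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_wlc_trajectory(seed, n_monomers=40, lb=3.8, lp=50.0, n_frames=5)
        sel = MucinSelection(1, 40, n_glycans=4, n_mucin_residues=40, bend_anchors=(1, 20, 40))
        Q, t = random_rigid_transform(rng)
        moved = PolymerTrajectory(
            traj.coordinates @ Q.T + t, traj.resids, traj.atom_names, traj.masses
        )
        np.testing.assert_allclose(
            end_to_end_series(traj, sel), end_to_end_series(moved, sel), rtol=1e-9
        )
        np.testing.assert_allclose(
            bending_angle_series(traj, sel), bending_angle_series(moved, sel),
            rtol=1e-7, atol=1e-7,
        )
        a = persistence_length(traj, sel, frame_window=5)
        b = persistence_length(moved, sel, frame_window=5)
        assert a.lp == pytest.approx(b.lp, rel=1e-9)


class TestBondAutocorrelation:
    def test_c0_is_exactly_one(self):
        traj = make_wlc_trajectory(1, n_monomers=30, lb=3.8, lp=30.0, n_frames=10)
        c = bond_autocorrelation(traj.coordinates)
        assert c[0] == 1.0
        assert np.all((c >= -1.0) & (c <= 1.0))

    def test_straight_rod_never_decorrelates(self):
        traj = straight_chain(50, 3.5, n_frames=3)
        sel = MucinSelection(1, 50, n_glycans=5, n_mucin_residues=50)
        res = persistence_length(traj, sel, frame_window=3)
        assert np.isinf(res.lp)
        assert not res.replicas[0].finite

    def test_freely_jointed_chain_has_tiny_lp(self):
        # deflection mean cosine ~0: lp should be on the order of one bond
        traj = make_wlc_trajectory(2, n_monomers=100, lb=3.8, lp=0.5, n_frames=400)
        sel = MucinSelection(1, 100, n_glycans=5, n_mucin_residues=100)
        res = persistence_length(traj, sel, frame_window=400)
        assert res.lp < 2.0


class TestPersistenceRecovery:
    @pytest.mark.parametrize("lp_true,seed", [(20.0, 11), (100.0, 12)])
    def test_wlc_recovery_within_15_percent(self, lp_true, seed):
        traj = make_wlc_trajectory(seed, n_monomers=200, lb=3.8, lp=lp_true, n_frames=800)
        sel = MucinSelection(1, 200, n_glycans=20, n_mucin_residues=200)
        res = persistence_length(traj, sel, frame_window=800)
        assert res.lp == pytest.approx(lp_true, rel=0.15)

    def test_agrees_with_mdanalysis_reference(self):
        """Cross-check the autocorrelation fit against the MDAnalysis
        polymer PersistenceLength tool on the same ensemble."""
        import MDAnalysis as mda
        from MDAnalysis.analysis import polymer

        traj = make_wlc_trajectory(21, n_monomers=80, lb=3.8, lp=60.0, n_frames=300)
        sel = MucinSelection(1, 80, n_glycans=8, n_mucin_residues=80)
        ours = persistence_length(traj, sel, frame_window=300)

        u = mda.Universe.empty(
            n_atoms=80, n_residues=80, atom_resindex=np.arange(80),
            residue_segindex=np.zeros(80, dtype=int), trajectory=True,
        )
        u.add_TopologyAttr("name", ["CA"] * 80)
        u.add_TopologyAttr("masses", np.full(80, 12.0))
        u.add_TopologyAttr("resids", np.arange(1, 81))
        u.load_new(traj.coordinates, order="fac")
        pl = polymer.PersistenceLength([u.select_atoms("name CA")])
        pl.run()
        assert ours.lp == pytest.approx(pl.results.lp, rel=0.15)

    def test_summary_mentions_replicas(self):
        trajs = [
            make_wlc_trajectory(s, n_monomers=60, lb=3.8, lp=40.0, n_frames=100,
                                replica_id=f"rep{s}")
            for s in (1, 2, 3)
        ]
        sel = MucinSelection(1, 60, n_glycans=6, n_mucin_residues=60)
        res = persistence_length(trajs, sel, frame_window=100)
        assert res.n_replicas == 3
        assert res.lp_sd >= 0.0
        text = res.summary()
        assert "rep1" in text and "lp mean" in text


class TestHeightPerGlycan:
    def test_straight_backbone(self):
        traj = straight_chain(181, 1.0)   # end-to-end 180 A
        sel = MucinSelection(1, 181, n_glycans=20, n_mucin_residues=181)
        value, sd = height_per_glycan(traj, sel, "outstretched")
        assert value == pytest.approx(9.0)
        assert sd == 0.0

    def test_single_glycan_equals_backbone_length(self):
        traj = straight_chain(11, 2.0)
        sel = MucinSelection(1, 11, n_glycans=1, n_mucin_residues=11)
        value, _ = height_per_glycan(traj, sel, "outstretched")
        assert value == pytest.approx(20.0)

    def test_compression_halves_value(self):
        traj = straight_chain(11, 2.0)
        compressed = PolymerTrajectory(
            traj.coordinates * 0.5, traj.resids, traj.atom_names, traj.masses
        )
        sel = MucinSelection(1, 11, n_glycans=2, n_mucin_residues=11)
        v1, _ = height_per_glycan(traj, sel, "equilibrated")
        v2, _ = height_per_glycan(compressed, sel, "equilibrated")
        assert v2 == pytest.approx(v1 / 2)

    def test_equilibrated_below_outstretched_for_flexible_chain(self):
        # frame 0 replaced by a straight chain: relaxed frames must be shorter
        wlc = make_wlc_trajectory(5, n_monomers=100, lb=3.8, lp=30.0, n_frames=200)
        coords = wlc.coordinates.copy()
        coords[0] = straight_chain(100, 3.8).coordinates[0]
        traj = PolymerTrajectory(coords, wlc.resids, wlc.atom_names, wlc.masses)
        sel = MucinSelection(1, 100, n_glycans=10, n_mucin_residues=100)
        out, _ = height_per_glycan(traj, sel, "outstretched")
        eq, _ = height_per_glycan(traj, sel, "equilibrated", frame_window=150)
        assert eq < out


class TestPdbReader:
    def test_multi_model_pdb_roundtrip(self, tmp_path):
        """Write a tiny multi-model PDB and read it back through MDAnalysis."""
        path = tmp_path / "chain.pdb"
        traj = straight_chain(5, 3.5, n_frames=2)
        lines = []
        for f in range(2):
            lines.append(f"MODEL     {f + 1}")
            for i in range(5):
                x, y, z = traj.coordinates[f, i]
                lines.append(
                    f"ATOM  {i + 1:5d}  CA  GLY A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        back = PolymerTrajectory.from_files(path, selection="name CA")
        assert back.n_frames == 2 and back.n_atoms == 5
        np.testing.assert_allclose(back.coordinates, traj.coordinates, atol=1e-3)
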