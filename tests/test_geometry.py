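"""Superposition, RMSF, salt-bridge occupancy/classification, the packaged
interaction-table fixture, axial shifts and pore-hydration profiles."""

import dataclasses
from importlib.resources import files

import numpy as np
import pytest

from hv1kit.geometry import (StructureEnsemble, axial_shift,
                             build_salt_bridge_table, dewetted_width,
                             hg_reference, parse_salt_bridge_table,
                             rmsd_series, rmsf, salt_bridge_occupancy,
                             SaltBridgeOccupancy, superpose,
                             water_axial_profile)
from hv1kit.synthetic import WaterSpec, generate_toy_ensemble

FIXTURE = files("hv1kit").joinpath("data/salt_bridge_table_hv1.tsv")


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent minimal-RMSD oracle via the Kearsley quaternion method:
    the smallest eigenvalue of the 4x4 key matrix gives the residual."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sm, sp = x - y, x + y
    xm, ym, zm = sm.T
    xp, yp, zp = sp.T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    K[1, 1] = np.sum(yp**2 + zp**2 + xm**2)
    K[2, 2] = np.sum(xp**2 + zp**2 + ym**2)
    K[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    K[0, 1] = K[1, 0] = np.sum(yp * zm - ym * zp)
    K[0, 2] = K[2, 0] = np.sum(xm * zp - xp * zm)
    K[0, 3] = K[3, 0] = np.sum(xp * ym - xm * yp)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xp * yp)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xp * zp)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - yp * zp)
    lam = np.linalg.eigvalsh(K)[0]
    return float(np.sqrt(max(lam, 0.0) / mobile.shape[0]))


def random_rigid(rng):
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return R, t


class TestSuperpose:
    def test_identical_frames_zero(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        _, rmsd = superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invisible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        R, t = random_rigid(rng)
        _, rmsd = superpose(X @ R.T + t, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle_on_random_pairs(self):
        """Kabsch RMSD equals the independent quaternion-method value to
        1e-6 A on 100 random 10-atom pairs."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            _, rmsd = superpose(A, B)
            assert rmsd == pytest.approx(quaternion_rmsd(A, B), abs=1e-6)

    def test_rmsd_invariant_under_rigid_motion_of_either_input(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(20, 3))
        B = A + rng.normal(scale=0.4, size=A.shape)
        _, base = superpose(A, B)
        R, t = random_rigid(rng)
        _, moved_a = superpose(A @ R.T + t, B)
        _, moved_b = superpose(A, B @ R.T + t)
        assert moved_a == pytest.approx(base, abs=1e-9)
        assert moved_b == pytest.approx(base, abs=1e-9)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdRmsf:
    def test_identical_frames_all_zero(self):
        d, _ = generate_toy_ensemble(6, 0.0, jitter_sd=0.0, seed=0)
        assert np.all(rmsd_series(d, d.frame(0)) < 1e-12)

    def test_jittered_ensemble_matches_gaussian_expectation(self):
        """Per-coordinate jitter s gives an expected RMSD between two
        independently jittered copies of s*sqrt(6) (two copies, three
        coordinates each); with many atoms the 6 rigid degrees of freedom
        absorbed by the superposition are negligible."""
        s, n_atoms = 0.5, 400
        rng = np.random.default_rng(1)
        base = rng.normal(scale=20.0, size=(n_atoms, 3))
        coords = base[None] + rng.normal(0.0, s, size=(100, n_atoms, 3))
        ens = StructureEnsemble(names=["CA"] * n_atoms,
                                resnames=["GLY"] * n_atoms,
                                resids=list(range(1, n_atoms + 1)),
                                coords=coords)
        series = rmsd_series(ens, ens.frame(0))[1:]
        assert np.mean(series) == pytest.approx(s * np.sqrt(6.0), rel=0.05)

    def test_single_frame_series(self):
        d, _ = generate_toy_ensemble(1, 0.0, jitter_sd=0.0, seed=2)
        assert rmsd_series(d, d.frame(0)).shape == (1,)

    def test_rmsf_rigid_ensemble_zero(self):
        d, _ = generate_toy_ensemble(5, 0.0, jitter_sd=0.0, seed=3)
        assert np.all(rmsf(d) < 1e-12)

    def test_rmsf_single_jittered_residue_closed_form(self):
        """One residue jittered isotropically with sigma = 1 A per
        coordinate has RMSF sqrt(3) A; the rigid rest stays near zero."""
        rng = np.random.default_rng(4)
        n_frames, n_static = 500, 30
        static = rng.normal(scale=10.0, size=(n_static, 3))
        coords = np.repeat(static[None], n_frames, axis=0)
        wobble = np.tile(np.array([12.0, 0.0, 0.0]), (n_frames, 1))
        wobble = wobble + rng.normal(0.0, 1.0, size=(n_frames, 3))
        coords = np.concatenate([coords, wobble[:, None, :]], axis=1)
        ens = StructureEnsemble(
            names=["CA"] * (n_static + 1), resnames=["GLY"] * (n_static + 1),
            resids=list(range(1, n_static + 2)), coords=coords)
        per_res = rmsf(ens)
        assert per_res.loc[n_static + 1] == pytest.approx(np.sqrt(3.0),
                                                          rel=0.10)
        assert per_res.loc[1] < 0.2

    def test_rmsf_two_frame_symmetric_displacement(self):
        """An atom displaced by +/- d/2 around its mean in a two-frame
        ensemble (anchored by many rigid atoms) has RMSF d/2."""
        rng = np.random.default_rng(5)
        n_static = 60
        static = rng.normal(scale=15.0, size=(n_static, 3))
        coords = np.repeat(static[None], 2, axis=0)
        mover = np.array([[5.0, 0.0, -1.0], [5.0, 0.0, 1.0]])
        coords = np.concatenate([coords, mover[:, None, :]], axis=1)
        ens = StructureEnsemble(names=["CA"] * (n_static + 1),
                                resnames=["GLY"] * (n_static + 1),
                                resids=list(range(1, n_static + 2)),
                                coords=coords)
        assert rmsf(ens).loc[n_static + 1] == pytest.approx(1.0, abs=0.05)

    def test_rmsf_single_frame_rejected(self):
        d, _ = generate_toy_ensemble(1, 0.0, seed=5)
        with pytest.raises(ValueError):
            rmsf(d)


def pair_ensemble(distances):
    """ARG205 NH1 at origin; ASP112 OD1 at the given distance per frame."""
    coords = np.zeros((len(distances), 2, 3))
    coords[:, 1, 0] = distances
    return StructureEnsemble(names=["NH1", "OD1"], resnames=["ARG", "ASP"],
                             resids=[205, 112], coords=coords)


class TestSaltBridges:
    def test_constant_contact_strong(self):
        occ = salt_bridge_occupancy(pair_ensemble([3.5] * 50),
                                    pairs=[(205, 112)])[0]
        assert occ.occupancy == 1.0 and occ.klass == "strong"

    def test_alternating_contact_weak(self):
        occ = salt_bridge_occupancy(pair_ensemble([3.5, 8.0] * 50),
                                    pairs=[(205, 112)])[0]
        assert occ.occupancy == pytest.approx(0.5)
        assert occ.klass == "weak"

    def test_never_in_contact_none(self):
        occ = salt_bridge_occupancy(pair_ensemble([8.0] * 50),
                                    pairs=[(205, 112)])[0]
        assert occ.occupancy == 0.0 and occ.klass == "none"

    def test_classification_monotone_in_cutoff(self):
        rank = {"none": 0, "weak": 1, "strong": 2}
        ens = pair_ensemble([3.2, 4.5, 5.1, 6.5] * 25)
        prev = -1
        for d_on in (3.0, 4.0, 5.0, 6.0, 7.0):
            occ = salt_bridge_occupancy(ens, pairs=[(205, 112)], d_on=d_on)[0]
            assert rank[occ.klass] >= prev
            prev = rank[occ.klass]

    def test_missing_sidechain_pair_skipped(self, caplog):
        ens = pair_ensemble([3.5] * 5)
        assert salt_bridge_occupancy(ens, pairs=[(205, 999)]) == []


class TestSaltBridgeTable:
    def test_fixture_sums_match_printed(self):
        tbl = parse_salt_bridge_table(FIXTURE)
        assert tbl.recompute_sums() == tbl.printed_sums
        assert tbl.printed_sums[("WT", "d")] == (7, 5)
        assert tbl.printed_sums[("G215E", "a")] == (12, 7)

    def test_build_round_trips_with_parser(self):
        tbl = parse_salt_bridge_table(FIXTURE)
        occs = {}
        occ_for = {"strong": 0.9, "weak": 0.4, "none": 0.0}
        for col in tbl.columns:
            occs[col] = [SaltBridgeOccupancy(pair=tuple(p.split("-")),
                                             occupancy=occ_for[tbl.cells[(p, col)]],
                                             klass=tbl.cells[(p, col)])
                         for p in tbl.pairs]
        rebuilt = build_salt_bridge_table(occs)
        assert rebuilt.cells == tbl.cells
        assert rebuilt.recompute_sums() == tbl.printed_sums

    def test_empty_table_zero_sums(self):
        tbl = build_salt_bridge_table({("X", "d"): []})
        assert tbl.recompute_sums() == {("X", "d"): (0, 0)}

    def test_unknown_glyph_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("\tWT\t\n\td\ta\nR1-D112\t?\t\n")
        with pytest.raises(ValueError, match="glyph"):
            parse_salt_bridge_table(bad)


class TestAxialGeometry:
    def test_hg_reference_at_construction_plane(self):
        d, _ = generate_toy_ensemble(10, 0.0, jitter_sd=0.0, seed=6)
        z0, (x0, y0) = hg_reference(d)
        assert z0 == pytest.approx(0.0, abs=1e-12)
        assert (x0, y0) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_hg_reference_translated(self):
        d, _ = generate_toy_ensemble(4, 0.0, jitter_sd=0.0, seed=7)
        shifted = StructureEnsemble(d.names, d.resnames, d.resids,
                                    d.coords + np.array([0.0, 0.0, 3.0]))
        assert hg_reference(shifted)[0] == pytest.approx(3.0)

    def test_missing_gasket_residue_errors(self):
        ens = pair_ensemble([3.5])
        with pytest.raises(ValueError, match="gasket"):
            hg_reference(ens)

    def test_axial_shift_recovered_and_antisymmetric(self):
        d, a = generate_toy_ensemble(50, 7.0, seed=8)
        s = axial_shift(d, a, [208])
        assert s == pytest.approx(7.0, abs=0.1)
        assert axial_shift(a, d, [208]) == pytest.approx(-s)
        assert axial_shift(d, d, [208]) == 0.0

    def test_helix_range_equals_per_residue_mean(self):
        d, a = generate_toy_ensemble(20, 5.0, seed=9)
        resids = [r for r in range(199, 219)]
        brute = np.mean([axial_shift(d, a, [r]) for r in resids
                         if d.select(resids=[r], names=["CA"]).size])
        assert axial_shift(d, a, resids) == pytest.approx(brute, abs=1e-9)

    def test_sidechain_tip_mode(self):
        d, a = generate_toy_ensemble(20, 6.0, seed=10)
        assert axial_shift(d, a, [208], atom_mode="sidechain_tip") == \
            pytest.approx(6.0, abs=0.1)


class TestWaterProfile:
    @pytest.mark.parametrize("slab", [4.5, 3.5])
    def test_dewetted_width_recovers_slab(self, slab):
        d, _ = generate_toy_ensemble(
            200, 0.0, waters=WaterSpec(exclusion_halfwidth=slab / 2), seed=11)
        prof = water_axial_profile(d)
        assert dewetted_width(prof) == pytest.approx(slab, abs=0.25)

    def test_dense_waters_no_exclusion_zero_width(self):
        d, _ = generate_toy_ensemble(100, 0.0, waters=WaterSpec(), seed=12)
        prof = water_axial_profile(d)
        assert dewetted_width(prof) == 0.0

    def test_no_waters_full_range_flagged(self):
        d, _ = generate_toy_ensemble(3, 0.0, waters=None, seed=13)
        prof = water_axial_profile(d)
        assert prof.no_waters
        assert dewetted_width(prof) == pytest.approx(
            prof.z_bins[-1] - prof.z_bins[0])
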