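import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edtomo import lattice, peaks, reconstruct, simulate
from edtomo.geometry import UnitCell, reciprocal_matrix, rotation_about_axis
from edtomo.lattice import (
    IndexParams,
    LatticeError,
    ReciprocalBasis,
    Reflections,
    absence_statistics,
    cell_parameters_from_basis,
    find_reciprocal_basis,
    index_reflections,
    integrate_reflection_3d,
    merge_spots,
)
from edtomo.reconstruct import TiltAxis


def spots_frame(g, frames, intensities, xy=None):
    g = np.asarray(g, dtype=float)
    if xy is None:
        xy = np.zeros((len(g), 2))
    return pd.DataFrame(
        {
            "gx": g[:, 0], "gy": g[:, 1], "gz": g[:, 2],
            "intensity": intensities, "frame": frames,
            "x": np.asarray(xy)[:, 0], "y": np.asarray(xy)[:, 1],
        }
    )


def reflections_at(points, intensities=None) -> Reflections:
    points = np.asarray(points, dtype=float)
    n = len(points)
    inten = np.ones(n) if intensities is None else np.asarray(intensities, float)
    norms = np.linalg.norm(points, axis=1)
    table = pd.DataFrame(
        {
            "gx": points[:, 0], "gy": points[:, 1], "gz": points[:, 2],
            "I_max": inten, "I_3d": inten, "single_member": False,
            "frame_of_max": np.arange(n), "x": 0.0, "y": 0.0,
            "d": np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1), np.inf),
            "n_members": 1, "saturated": False,
        }
    )
    return Reflections(table=table, members=[np.array([i]) for i in range(n)])


class TestIntegrate3D:
    def test_hand_example(self):
        # intensities [1,2,1] at equal spacing 0.01: sum over i=2..3 of
        # I_i * |dK| = (2+1)*0.01
        pos = np.array([[0, 0, 0.00], [0, 0, 0.01], [0, 0, 0.02]])
        i3d, single = integrate_reflection_3d(pos, np.array([1.0, 2.0, 1.0]))
        assert not single
        assert i3d == pytest.approx(0.03)

    def test_single_member_fallback(self):
        i3d, single = integrate_reflection_3d(np.array([[0, 0, 0.1]]), np.array([7.0]))
        assert single and i3d == 7.0

    def test_homogeneous_in_spacing(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.uniform(0.001, 0.01, (6, 3)), axis=0)
        inten = rng.uniform(1, 100, 6)
        a, _ = integrate_reflection_3d(pos, inten)
        b, _ = integrate_reflection_3d(2.0 * pos, inten)
        assert b == pytest.approx(2.0 * a)

    @settings(max_examples=50)
    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, n, seed):
        """Independently coded sum: loop i=1..n-1 over python floats."""
        rng = np.random.default_rng(seed)
        pos = rng.normal(size=(n, 3))
        inten = rng.uniform(0, 1000, n)
        expected = 0.0
        for i in range(1, n):
            dk = np.sqrt(float(np.sum((pos[i] - pos[i - 1]) ** 2)))
            expected += float(inten[i]) * dk
        got, single = integrate_reflection_3d(pos, inten)
        assert not single
        assert got == pytest.approx(expected, rel=1e-12)


class TestMerge:
    def test_singleton(self):
        sp = spots_frame([[0.1, 0.0, 0.0]], [4], [42.0], [[200.0, 100.0]])
        refl = merge_spots(sp)
        assert len(refl) == 1
        row = refl.table.iloc[0]
        assert row.I_max == 42.0 and row.frame_of_max == 4 and row.single_member
        np.testing.assert_allclose([row.gx, row.gy, row.gz], [0.1, 0, 0])

    def test_weighted_mean_position(self):
        sp = spots_frame(
            [[0.100, 0, 0], [0.104, 0, 0]], [0, 1], [3.0, 1.0], [[10, 10], [10, 10]]
        )
        refl = merge_spots(sp, merge_3d_radius=0.02)
        assert len(refl) == 1
        assert refl.table.gx[0] == pytest.approx((0.3 + 0.104) / 4.0)

    def test_frame_gap_breaks_groups(self):
        sp = spots_frame(
            [[0.1, 0, 0], [0.1, 0, 0]], [0, 10], [1.0, 1.0], [[10, 10], [10, 10]]
        )
        assert len(merge_spots(sp, max_frame_gap=3)) == 2

    def test_2d_distance_breaks_groups(self):
        sp = spots_frame(
            [[0.1, 0, 0], [0.1, 0, 0]], [0, 1], [1.0, 1.0], [[10, 10], [300, 300]]
        )
        assert len(merge_spots(sp, merge_2d_radius=8.0)) == 2

    def test_noiseless_counts_match_truth(self, clean_sim):
        ts = clean_sim.truth_spots()
        s3 = reconstruct.map_to_3d(
            ts, clean_sim.info, TiltAxis(clean_sim.config.tilt_axis_azimuth_true),
            intensity_column="integrated",
        )
        refl = merge_spots(s3)
        keep = reconstruct._dedup_frame_selector(clean_sim.info)
        truth = ts[keep[ts["frame"].to_numpy()]]
        assert len(refl) == truth.groupby(["h", "k", "l"]).ngroups

    def test_friedel_mates_stay_separate(self, clean_sim):
        ts = clean_sim.truth_spots()
        s3 = reconstruct.map_to_3d(
            ts, clean_sim.info, TiltAxis(clean_sim.config.tilt_axis_azimuth_true),
            intensity_column="integrated",
        )
        refl = merge_spots(s3)
        basis = ReciprocalBasis(clean_sim.truth.basis)
        idx = index_reflections(refl, basis)
        acc = idx[idx.accepted]
        keys = set(map(tuple, acc[["h", "k", "l"]].to_numpy()))
        mates = sum((-h, -k, -l) in keys for h, k, l in keys)
        assert mates > 0.5 * len(keys)  # both mates present as separate rows


class TestBasis:
    def test_exact_lattice_points(self):
        b_true = np.array([[0.1, 0, 0], [0, 0.08, 0], [0.01, 0, 0.12]])
        hkl = np.mgrid[-3:4, -3:4, -3:4].reshape(3, -1).T
        pts = hkl @ b_true
        basis, clusters = find_reciprocal_basis(pts, min_pts=3)
        # found basis spans the same lattice: integer unimodular transform
        m = np.linalg.solve(b_true.T, basis.vectors.T).T
        np.testing.assert_allclose(m, np.rint(m), atol=1e-9)
        assert abs(np.linalg.det(np.rint(m))) == pytest.approx(1.0)

    def test_noiseless_sim_unimodular(self, clean_sim):
        ts = clean_sim.truth_spots()
        s3 = reconstruct.map_to_3d(
            ts, clean_sim.info, TiltAxis(clean_sim.config.tilt_axis_azimuth_true),
            intensity_column="integrated",
        )
        refl = merge_spots(s3)
        basis, _ = find_reciprocal_basis(refl)
        m = np.linalg.solve(clean_sim.truth.basis.T, basis.vectors.T).T
        np.testing.assert_allclose(m, np.rint(m), atol=0.05)
        assert abs(round(np.linalg.det(np.rint(m)))) == 1

    def test_collinear_fails(self):
        pts = np.outer(np.arange(-20, 21), np.array([0.1, 0.0, 0.0]))
        with pytest.raises(LatticeError):
            find_reciprocal_basis(pts, min_pts=3)

    def test_rotation_invariance(self, clean_sim):
        ts = clean_sim.truth_spots()
        s3 = reconstruct.map_to_3d(
            ts, clean_sim.info, TiltAxis(clean_sim.config.tilt_axis_azimuth_true),
            intensity_column="integrated",
        )
        refl = merge_spots(s3)
        basis_a, _ = find_reciprocal_basis(refl)
        cell_a = cell_parameters_from_basis(basis_a)
        rot = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 0.7)
        g = refl.g @ rot.T
        basis_b, _ = find_reciprocal_basis(g)
        cell_b = cell_parameters_from_basis(basis_b)
        np.testing.assert_allclose(
            sorted(cell_a.parameters()[:3]), sorted(cell_b.parameters()[:3]), rtol=1e-6
        )


class TestCellFromBasis:
    def test_orthonormal_scaled(self):
        basis = ReciprocalBasis(np.eye(3) * 0.1)
        cell = cell_parameters_from_basis(basis)
        np.testing.assert_allclose(
            cell.parameters(), [10, 10, 10, 90, 90, 90], rtol=1e-12
        )

    def test_identity_transform_noop(self):
        basis = ReciprocalBasis(reciprocal_matrix(UnitCell(11, 13, 7, 85, 93, 99)))
        a = cell_parameters_from_basis(basis)
        b = cell_parameters_from_basis(basis, transform=np.eye(3))
        np.testing.assert_allclose(a.parameters(), b.parameters())

    def test_transform_doubles_axis(self):
        basis = ReciprocalBasis(np.eye(3) * 0.1)
        t = np.diag([1.0, 1.0, 0.5])  # halve c* -> double c
        with pytest.raises(ValueError):
            cell_parameters_from_basis(basis, transform=t)
        t2 = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        cell = cell_parameters_from_basis(basis, transform=t2)
        assert cell.gamma != pytest.approx(90.0)

    def test_coplanar_rejected(self):
        with pytest.raises(ValueError):
            ReciprocalBasis(np.array([[0.1, 0, 0], [0, 0.1, 0], [0.1, 0.1, 0]]))


class TestIndexing:
    def test_near_integer_accepted(self):
        b = np.eye(3) * 0.1
        pts = np.array([[0.097, 0.095, 0.001]])
        idx = index_reflections(reflections_at(pts), ReciprocalBasis(b))
        row = idx.iloc[0]
        assert (row.h, row.k, row.l) == (1, 1, 0)
        assert row.accepted
        np.testing.assert_allclose(
            [row.h_frac, row.k_frac, row.l_frac], [0.97, 0.95, 0.01], atol=1e-12
        )

    def test_threshold_rejection(self):
        b = np.eye(3) * 0.1
        pts = np.array([[0.115, 0.1, 0.0]])  # h_frac = 1.15
        idx = index_reflections(
            reflections_at(pts), ReciprocalBasis(b), IndexParams(threshold=0.1)
        )
        assert not idx.iloc[0].accepted
        assert idx.iloc[0].deviation == pytest.approx(0.15)

    def test_exact_nodes_deviation_tiny(self):
        b_true = reciprocal_matrix(UnitCell(12, 14, 10))
        hkl = np.mgrid[-4:5, -4:5, -4:5].reshape(3, -1).T
        hkl = hkl[np.any(hkl != 0, axis=1)]
        pts = hkl @ b_true
        idx = index_reflections(reflections_at(pts), ReciprocalBasis(b_true))
        assert idx.accepted.all()
        assert idx.deviation.max() < 1e-6
        np.testing.assert_array_equal(idx[["h", "k", "l"]].to_numpy(), hkl)

    def test_adaptive_indexing_with_axis_off_two_degrees(self, clean_sim):
        """Reconstruction with a deliberately wrong axis still indexes
        >= 99% of reflections to their true hkl."""
        ts = clean_sim.truth_spots()
        s3 = reconstruct.map_to_3d(
            ts, clean_sim.info,
            TiltAxis(clean_sim.config.tilt_axis_azimuth_true + 2.0),
            intensity_column="integrated",
        )
        refl = merge_spots(s3)
        idx = index_reflections(refl, ReciprocalBasis(clean_sim.truth.basis))
        keep = reconstruct._dedup_frame_selector(clean_sim.info)
        truth = ts[keep[ts["frame"].to_numpy()]]
        tkey = {
            (int(r.frame), round(r.x, 3), round(r.y, 3)): (int(r.h), int(r.k), int(r.l))
            for r in truth.itertuples()
        }
        good = tot = 0
        for r in idx.itertuples():
            key = (int(r.frame_of_max), round(r.x, 3), round(r.y, 3))
            if key in tkey:
                tot += 1
                good += (r.h, r.k, r.l) == tkey[key]
        assert tot > 0.9 * len(idx)
        assert good / tot >= 0.99

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            IndexParams(threshold=0.7).thresholds()


class TestAbsences:
    def test_constant_intensities(self):
        df = pd.DataFrame(
            {
                "h": [1, 2, 0, 1], "k": [1, 0, 1, 0], "l": [0, 0, 1, 1],
                "I_max": [1.0] * 4, "accepted": [True] * 4,
            }
        )
        stats = absence_statistics(df)
        populated = stats[stats.n > 0]
        assert (populated.mean_I == 1.0).all()

    def test_empty_class_nan_safe(self):
        df = pd.DataFrame(
            {"h": [2], "k": [2], "l": [2], "I_max": [5.0], "accepted": [True]}
        )
        stats = absence_statistics(df)
        odd = stats[stats["class"] == "h+k+l odd"].iloc[0]
        assert odd.n == 0 and np.isnan(odd.mean_I)

    def test_extinct_classes_dark(self, tmp_path):
        """Frames rendered under an extinction rule: intensity extracted at
        would-be extinct positions stays at background residual level."""
        from conftest import small_sim_config
        from edtomo.io import TiltSchedule, read_frame_stack

        sched = TiltSchedule(-20.0, 20.0, 2.0, 0.9, 0.3)
        base = dict(
            seed=13, schedule=sched, poisson_noise=False, drift_step_sigma=0.0
        )
        cfg_ext = small_sim_config(extinction=simulate.extinct_p21n, **base)
        cfg_all = small_sim_config(extinction=None, **base)
        info, _ = simulate.render_dataset(cfg_ext, tmp_path)
        stack = read_frame_stack(info, tmp_path)
        extinct_i, present_i = [], []
        for fr in range(0, stack.n_frames, 4):
            proj = simulate.frame_projection(cfg_all, info.frames[fr].combined_tilt)
            if len(proj) == 0:
                continue
            sp = pd.DataFrame(
                {
                    "frame": fr, "x": proj.x, "y": proj.y, "raw": 0.0,
                    "smoothed": 0.0, "integrated": np.nan,
                    "saturated": False, "partial": False,
                }
            )
            out = peaks.extract_intensities(stack.data[fr], sp, mode="integrated")
            mask = simulate.extinct_p21n(proj[["h", "k", "l"]].to_numpy())
            extinct_i.extend(out.integrated.to_numpy()[mask])
            present_i.extend(out.integrated.to_numpy()[~mask])
        assert len(extinct_i) > 3 and len(present_i) > 30
        assert np.mean(np.abs(extinct_i)) < 0.02 * np.mean(present_i)
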