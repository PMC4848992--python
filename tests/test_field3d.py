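"""Lattice construction, probe fields, column filtering, NIPALS PLS, contours."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from anthraqsar.chemio import AlignedConformer
from anthraqsar.field3d import (
    COULOMB_CONSTANT,
    LJ_PARAMS,
    PROBE_EPSILON,
    PROBE_RADIUS,
    FieldBlock,
    build_lattice,
    column_filter,
    compute_field_block,
    contour_grid,
    electrostatic_field,
    fit_pls,
    select_components,
    steric_field,
    write_opendx,
)


def _mol(xyz, q=None, radius=1.7, elem="C"):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    return AlignedConformer(
        tuple([elem] * n), xyz,
        np.zeros(n) if q is None else np.asarray(q, dtype=float),
        np.full(n, radius),
    )


class TestLattice:
    def test_single_atom_margin(self):
        lat = build_lattice([_mol([[0, 0, 0]])], spacing=2.0, margin=4.0)
        pts = lat.points()
        assert pts.min() <= -4.0 and pts.max() >= 4.0
        assert all(d >= 5 for d in lat.dims)

    def test_translation_equivariance(self):
        mols = [_mol([[0, 0, 0], [2, 1, 0]])]
        lat0 = build_lattice(mols, spacing=2.0)
        shifted = [_mol(m.xyz + np.array([10.0, 0, 0])) for m in mols]
        lat1 = build_lattice(shifted, spacing=2.0)
        assert lat1.dims == lat0.dims
        assert lat1.origin[0] == pytest.approx(lat0.origin[0] + 10.0)
        assert lat1.origin[1:] == pytest.approx(lat0.origin[1:])

    def test_span_plus_margins(self):
        lat = build_lattice([_mol([[0, 0, 0], [6, 0, 0]])], spacing=2.0, margin=4.0)
        extent = lat.spacing * (lat.dims[0] - 1)
        assert extent >= 14.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_lattice([], spacing=2.0)


class TestStericField:
    def test_minimum_at_rmin(self):
        conf = _mol([[0, 0, 0]])
        rmin = 1.7 + PROBE_RADIUS
        e = steric_field(conf, np.array([[rmin, 0, 0]]))
        eps = np.sqrt(LJ_PARAMS["C"] * PROBE_EPSILON)
        assert e[0] == pytest.approx(-eps, rel=1e-9)

    def test_vanishes_far_away(self):
        e = steric_field(_mol([[0, 0, 0]]), np.array([[80.0, 0, 0]]))
        assert abs(e[0]) < 1e-6

    def test_truncated_at_cutoff(self):
        rmin = 1.7 + PROBE_RADIUS
        e = steric_field(_mol([[0, 0, 0]]), np.array([[0.5 * rmin, 0, 0]]))
        assert e[0] == 30.0

    def test_atom_coincident_with_point(self):
        e = steric_field(_mol([[0, 0, 0]]), np.array([[0.0, 0, 0]]))
        assert e[0] == 30.0

    def test_never_exceeds_cutoff_on_grid(self):
        conf = _mol([[0, 0, 0], [1.2, 0.3, -0.5]])
        lat = build_lattice([conf], spacing=1.0, margin=3.0)
        e = steric_field(conf, lat)
        assert e.max() <= 30.0 + 1e-12


class TestElectrostaticField:
    def test_neutral_molecule_zero(self):
        conf = _mol([[0, 0, 0], [2, 0, 0]])
        e, _ = electrostatic_field(conf, np.array([[5.0, 0, 0]]))
        np.testing.assert_allclose(e, 0.0)

    def test_hand_value_distance_dielectric(self):
        # q=+0.5, probe +1, r=4: 332.0636*0.5/16
        conf = _mol([[0, 0, 0]], q=[0.5])
        e, buried = electrostatic_field(conf, np.array([[4.0, 0, 0]]))
        assert not buried[0]
        assert e[0] == pytest.approx(COULOMB_CONSTANT * 0.5 / 16.0, rel=1e-9)
        assert e[0] == pytest.approx(10.377, abs=1e-3)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(scale=2, size=(4, 3))
        q = rng.normal(scale=0.3, size=4)
        pts = rng.normal(scale=5, size=(30, 3))
        e_pos, b1 = electrostatic_field(_mol(xyz, q=q), pts)
        e_neg, b2 = electrostatic_field(_mol(xyz, q=-q), pts)
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_allclose(e_pos[~b1], -e_neg[~b1], atol=1e-9)

    def test_clipped_to_cutoff(self):
        conf = _mol([[0, 0, 0]], q=[1.0])
        e, _ = electrostatic_field(conf, np.array([[1.9, 0, 0]]))
        assert e[0] == 30.0

    def test_buried_points_filled_with_column_mean(self):
        # one molecule has an atom at the origin (buries the point), the
        # other does not; the buried entry must equal the unburied mean
        lat_pts = np.array([[0.0, 0.0, 0.0]])
        m1 = _mol([[0.0, 0, 0]], q=[0.3])
        m2 = _mol([[5.0, 0, 0]], q=[0.3])
        lat = build_lattice([m1, m2], spacing=2.0, margin=4.0)
        block = compute_field_block([m1, m2], lat)
        # locate the column of the origin point in the electrostatic block
        pts = lat.points()
        j = int(np.argmin(np.linalg.norm(pts, axis=1)))
        col = block.matrix[:, block.n_points + j]
        e2, buried2 = electrostatic_field(m2, pts[j : j + 1])
        assert not buried2[0]
        assert col[0] == pytest.approx(col[1])
        assert col[1] == pytest.approx(e2[0])


class TestRigidMotionInvariance:
    def test_field_matrix_unchanged_under_joint_rotation(self):
        rng = np.random.default_rng(1)
        mols = [
            _mol(rng.normal(scale=1.5, size=(3, 3)), q=rng.normal(scale=0.2, size=3))
            for _ in range(3)
        ]
        lat = build_lattice(mols, spacing=2.0, margin=4.0)
        pts = lat.points()
        R = Rotation.from_euler("xyz", [0.4, -0.8, 1.2]).as_matrix()
        t = np.array([2.0, -1.0, 3.0])
        rot_pts = pts @ R.T + t
        for m in mols:
            m_rot = _mol(m.xyz @ R.T + t, q=m.charges)
            np.testing.assert_allclose(
                steric_field(m, pts), steric_field(m_rot, rot_pts), atol=1e-6
            )
            e0, b0 = electrostatic_field(m, pts)
            e1, b1 = electrostatic_field(m_rot, rot_pts)
            np.testing.assert_array_equal(b0, b1)
            np.testing.assert_allclose(e0, e1, atol=1e-6)


class TestColumnFilter:
    def _block(self, M):
        lat = build_lattice([_mol([[0, 0, 0]])], spacing=2.0)
        P = M.shape[1] // 2
        return FieldBlock(M, lat, np.arange(M.shape[1]))

    def test_constant_column_dropped(self):
        M = np.array([[1.0, 0.0], [1.0, 20.0]])
        fb = column_filter(self._block(M), sigma_min=6.0)
        assert fb.retained_columns.tolist() == [1]

    def test_sd_ten_retained_at_six(self):
        M = np.array([[0.0, 0.0], [20.0, 0.0]])
        fb = column_filter(self._block(M), sigma_min=6.0)
        assert fb.retained_columns.tolist() == [0]

    def test_matches_direct_sd_oracle(self):
        rng = np.random.default_rng(2)
        M = rng.normal(scale=8, size=(6, 10))
        fb = column_filter(self._block(M), sigma_min=6.0)
        expect = [j for j in range(10) if M[:, j].std() >= 6.0]
        assert fb.retained_columns.tolist() == expect

    def test_all_filtered_raises(self):
        M = np.zeros((3, 4))
        with pytest.raises(ValueError, match="sigma_min"):
            column_filter(self._block(M), sigma_min=6.0)


def _numeric_block(X, n_steric=None):
    """Wrap a plain matrix as a FieldBlock (first half steric by default)."""
    lat = build_lattice([_mol([[0, 0, 0]])], spacing=2.0)
    n, p = X.shape
    M = X
    if p % 2:
        M = np.hstack([X, np.zeros((n, 1))])
    return FieldBlock(M, lat, np.arange(X.shape[1]))


class TestPLS:
    def test_single_informative_column(self):
        rng = np.random.default_rng(3)
        X = np.zeros((10, 4))
        X[:, 1] = rng.normal(size=10)
        X[:, 3] = 0.0
        y = 2.0 + 3.0 * X[:, 1]
        block = _numeric_block(X)
        m = fit_pls(block, y, 1, scaling="none")
        assert m.r2 == pytest.approx(1.0, abs=1e-10)
        # column 1 lies in the steric half -> all contribution mass there
        assert m.contributions[0] == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        block = _numeric_block(X)
        m = fit_pls(block, y, 4, scaling="none")
        D = np.column_stack([np.ones(12), X])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        pred_ols = D @ beta
        pred_pls = m.intercept + X @ m.coefficients
        np.testing.assert_allclose(pred_pls, pred_ols, atol=1e-6)

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        m = fit_pls(_numeric_block(X), y, 3)
        assert sum(m.contributions) == pytest.approx(1.0, abs=1e-9)

    def test_recall_r2_nondecreasing_in_components(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 15)
        block = _numeric_block(X)
        r2s = [fit_pls(block, y, a, scaling="none").r2 for a in range(1, 7)]
        assert all(a <= b + 1e-9 for a, b in zip(r2s, r2s[1:]))

    def test_zero_variance_y_rejected(self):
        X = np.random.default_rng(7).normal(size=(8, 4))
        with pytest.raises(ValueError):
            fit_pls(_numeric_block(X), np.ones(8), 2)


class TestSelectComponents:
    def test_rank_one_noiseless(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=6))
        y = 2.0 * t + 1.0
        n_star, q2 = select_components(_numeric_block(X), y, 4, scaling="none")
        assert n_star == 1
        assert q2 == pytest.approx(1.0, abs=1e-8)

    def test_three_latent_components_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            T = rng.normal(size=(30, 3))
            P = rng.normal(size=(3, 12))
            X = T @ P + rng.normal(0, 0.02, size=(30, 12))
            y = T @ [2.0, -1.5, 1.0] + rng.normal(0, 0.05, 30)
            n_star, _ = select_components(_numeric_block(X), y, 6, scaling="none")
            hits += n_star == 3
        assert hits >= 9

    def test_argmax_contract(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(14, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.3, 14)
        block = _numeric_block(X)
        n_star, q2 = select_components(block, y, 5, scaling="none")
        from anthraqsar.field3d import _loo_q2

        all_q2 = [_loo_q2(block, y, a, "none") for a in range(1, 6)]
        assert q2 == pytest.approx(max(all_q2))
        assert n_star == int(np.argmax(all_q2)) + 1


class TestContourGrid:
    def test_zero_coefficients_zero_grid(self):
        rng = np.random.default_rng(10)
        X = np.abs(rng.normal(size=(8, 8))) + 0.5
        block = _numeric_block(X)
        m = fit_pls(block, rng.normal(size=8), 2, scaling="none")
        from dataclasses import replace

        m0 = replace(m, coefficients=np.zeros_like(m.coefficients))
        g = contour_grid(m0, block)
        assert np.all(g.steric == 0) and np.all(g.electrostatic == 0)

    def test_dominant_positive_steric_point_inside_favored_contour(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 8))
        y = 5.0 * X[:, 2] + rng.normal(0, 0.05, 10)  # steric column 2 drives y
        block = _numeric_block(X)
        m = fit_pls(block, y, 2, scaling="none")
        g = contour_grid(m, block)
        assert g.steric[2] >= g.steric_thresholds[1]

    def test_percentile_levels_match_sort_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.2, 12)
        block = _numeric_block(X)
        m = fit_pls(block, y, 3, scaling="none")
        g = contour_grid(m, block, favored_level=80, disfavored_level=20)
        vals = np.concatenate([g.steric, g.electrostatic])
        for v, (dis, fav) in (
            (g.steric, g.steric_thresholds),
            (g.electrostatic, g.electrostatic_thresholds),
        ):
            pos, neg = np.sort(v[v > 0]), np.sort(v[v < 0])
            if pos.size:
                assert fav == pytest.approx(np.percentile(pos, 80), abs=1e-9)
            if neg.size:
                assert dis == pytest.approx(np.percentile(neg, 20), abs=1e-9)

    def test_invalid_levels(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 6))
        block = _numeric_block(X)
        m = fit_pls(block, rng.normal(size=8), 2, scaling="none")
        with pytest.raises(ValueError):
            contour_grid(m, block, favored_level=20, disfavored_level=80)


class TestOpenDXExport:
    def test_roundtrippable_header_and_size(self, tmp_path):
        lat = build_lattice([_mol([[0, 0, 0]])], spacing=2.0, margin=4.0)
        vals = np.arange(lat.n_points, dtype=float)
        out = tmp_path / "grid.dx"
        write_opendx(vals, lat, out)
        text = out.read_text()
        nx, ny, nz = lat.dims
        assert f"counts {nx} {ny} {nz}" in text
        assert f"items {lat.n_points}" in text
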