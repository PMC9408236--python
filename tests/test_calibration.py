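"""Hadamard pattern construction, RVITM estimation, focus selection,
scan grid and acquisition timing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmfpam import (DMDPattern, acquire_calibration, acquisition_timing,
                    analytic_rvitm_oracle, build_hadamard_pattern_set,
                    characterise_all_planes, estimate_rvitm, generate_tm,
                    generate_tm_stack, make_scan_grid, propagate,
                    reference_field, select_focus_pattern)
from mmfpam.calibration import (SpeckleMeasurementSet,
                                select_focus_pattern_from_row)


class TestHadamardPatternSet:
    def test_order_two_base_case(self):
        ps = build_hadamard_pattern_set(2)
        assert np.array_equal(ps.H, [[1, 1], [1, -1]])
        assert np.array_equal(ps.H1, [[1, 1], [1, 0]])
        assert np.array_equal(ps.H2, [[0, 0], [0, 1]])

    @pytest.mark.parametrize("n", [2, 4, 16, 64])
    def test_binary_decomposition_and_orthogonality(self, n):
        ps = build_hadamard_pattern_set(n)
        assert np.array_equal(ps.H1 + ps.H2, np.ones((n, n)))
        assert np.array_equal(ps.H1.astype(int) - ps.H2, ps.H)
        assert np.array_equal(ps.H.T @ ps.H, n * np.eye(n))
        # [H,-H] . [H,-H]^T = 2N I
        b = ps.basis.astype(int)
        assert np.array_equal(b @ b.T, 2 * n * np.eye(n))

    def test_display_sequence_endpoints(self):
        ps = build_hadamard_pattern_set(8)
        assert np.all(ps.pattern(0).mask == 1)         # first H1: all-ON
        assert np.all(ps.pattern(8).mask == 0)         # first H2: all-OFF

    @pytest.mark.parametrize("bad", [0, 1, 3, 12])
    def test_rejects_non_power_of_two(self, bad):
        with pytest.raises(ValueError):
            build_hadamard_pattern_set(bad)


class TestAcquireCalibration:
    def test_all_off_and_all_on_columns(self, toy_tm, had4):
        meas = acquire_calibration(toy_tm, had4)
        ref = reference_field(toy_tm)
        assert meas.intensities[0, 4] == pytest.approx(0.0)   # all-OFF
        assert meas.intensities[0, 0] == pytest.approx(
            ref.amplitude[0, 0] ** 2)                          # all-ON
        assert meas.intensities.shape == (1, 8)

    def test_toy_columns_match_field_arithmetic(self, toy_tm, had4):
        """Every column equals 1/4 |E_R ± S_k|^2 with S_k = sum h_k t."""
        t = toy_tm.entries[0, 0]
        e_r = t.sum()
        meas = acquire_calibration(toy_tm, had4)
        for k in range(4):
            s_k = (had4.H[:, k] * t).sum()
            assert meas.intensities[0, k] == pytest.approx(
                0.25 * abs(e_r + s_k) ** 2)
            assert meas.intensities[0, 4 + k] == pytest.approx(
                0.25 * abs(e_r - s_k) ** 2)

    def test_matches_per_pattern_propagation(self, had4):
        tm = generate_tm(4, (5, 5), seed=1)
        meas = acquire_calibration(tm, had4)
        for k in range(8):
            img = propagate(tm, had4.pattern(k))
            assert np.allclose(meas.intensities[:, k], img.intensity.ravel())

    def test_dimension_mismatch_rejected(self, toy_tm):
        with pytest.raises(ValueError):
            acquire_calibration(toy_tm, build_hadamard_pattern_set(8))


class TestEstimateRVITM:
    def test_toy_case_exact(self, toy_tm, had4):
        rv = estimate_rvitm(acquire_calibration(toy_tm, had4), had4)
        assert np.allclose(rv.matrix, [[24.0, 8.0, 24.0, 24.0]], atol=1e-12)

    def test_zero_measurements_give_zero_rvitm(self, had4):
        meas = SpeckleMeasurementSet(np.zeros((3, 8)), (3, 1))
        assert np.all(estimate_rvitm(meas, had4).values == 0)

    def test_reference_offset_cancels(self, had4):
        """Replacing the subtracted all-ON intensity by any constant
        leaves the estimate unchanged ([H,-H]^T annihilates constants)."""
        tm = generate_tm(4, (3, 3), seed=2)
        meas = acquire_calibration(tm, had4)
        rv = estimate_rvitm(meas, had4)
        shifted = 2.0 * meas.intensities - 123.456
        alt = shifted @ had4.basis.T.astype(float)
        assert np.allclose(alt, rv.matrix, atol=1e-9)

    def test_wrong_column_count_rejected(self, had4):
        with pytest.raises(ValueError):
            estimate_rvitm(SpeckleMeasurementSet(np.zeros((1, 6)), (1, 1)),
                           had4)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_oracle_equivalence_noiseless(self, n):
        """Intensity-only estimation reproduces
        2N A_R A_mn cos(theta_mn - phi_R) to 1e-9 relative error."""
        ps = build_hadamard_pattern_set(n)
        for seed in range(5):
            tm = generate_tm(n, (8, 8), seed=seed)
            est = estimate_rvitm(acquire_calibration(tm, ps), ps).matrix
            ora = analytic_rvitm_oracle(tm).matrix
            err = np.linalg.norm(est - ora) / np.linalg.norm(ora)
            assert err <= 1e-9


class TestFocusPatternSelection:
    def test_toy_row_tie_break(self):
        fp = select_focus_pattern_from_row(
            np.array([24.0, 8.0, 24.0, 24.0]), (0, 0), 0.3)
        assert np.array_equal(fp.pattern.mask, [1, 0, 1, 0])

    def test_fraction_one_all_on(self, toy_tm, had4):
        rv = estimate_rvitm(acquire_calibration(toy_tm, had4), had4)
        fp = select_focus_pattern(rv, (0, 0), 1.0)
        assert np.all(fp.pattern.mask == 1)

    def test_all_equal_row_takes_lowest_indices(self):
        fp = select_focus_pattern_from_row(np.ones(10), (0, 0), 0.3)
        assert np.array_equal(np.flatnonzero(fp.pattern.mask), [0, 1, 2])

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            select_focus_pattern_from_row(np.ones(4), (0, 0), bad)

    def test_selection_invariant_to_intensity_rescaling(self, had4):
        tm = generate_tm(4, (3, 3), seed=4)
        meas = acquire_calibration(tm, had4)
        scaled = SpeckleMeasurementSet(37.0 * meas.intensities,
                                       meas.grid_shape)
        a = select_focus_pattern(estimate_rvitm(meas, had4), (1, 1))
        b = select_focus_pattern(estimate_rvitm(scaled, had4), (1, 1))
        assert np.array_equal(a.pattern.mask, b.pattern.mask)

    @given(st.integers(2, 7).map(lambda k: 2**k),
           st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_on_count_is_ceil_of_fraction(self, n, frac):
        rng = np.random.default_rng(0)
        fp = select_focus_pattern_from_row(rng.normal(size=n), (0, 0), frac)
        assert fp.pattern.mask.sum() == int(np.ceil(frac * n))

    def test_positive_rvitm_mirrors_interfere_constructively(self):
        """Selected mirrors with positive rvitm have output phase within
        pi/2 of the reference phase (simulator ground truth)."""
        tm = generate_tm(64, (9, 9), seed=6)
        ps = build_hadamard_pattern_set(64)
        rv = estimate_rvitm(acquire_calibration(tm, ps), ps)
        pix = (4, 4)
        fp = select_focus_pattern(rv, pix, 0.3)
        row = rv.values[pix]
        ref_phase = np.angle(tm.entries[pix].sum())
        for n in np.flatnonzero(fp.pattern.mask):
            if row[n] > 0:
                assert np.cos(np.angle(tm.entries[pix][n]) - ref_phase) > 0


class TestScanGrid:
    def test_tiny_grid_by_hand(self):
        g = make_scan_grid(2.0, 1.0)
        assert g.n_positions == 5
        assert {tuple(p) for p in g.positions_um} == {
            (0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)}

    def test_position_counts_match_disc_area(self):
        assert make_scan_grid(100, 1.0).n_positions == pytest.approx(
            7850, rel=0.01)
        assert make_scan_grid(100, 0.5).n_positions == pytest.approx(
            31500, rel=0.01)

    def test_raster_row_major_order(self):
        g = make_scan_grid(4.0, 1.0)
        ys = g.positions_um[:, 1]
        assert (np.diff(ys) >= 0).all()
        for y in np.unique(ys):
            xs = g.positions_um[ys == y, 0]
            assert (np.diff(xs) > 0).all()

    @given(st.floats(2.0, 60.0), st.floats(0.3, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_all_positions_inside_fov(self, diameter, step):
        g = make_scan_grid(diameter, step)
        r = np.hypot(g.positions_um[:, 0], g.positions_um[:, 1])
        assert (r <= diameter / 2 * (1 + 1e-6)).all()
        assert any((g.positions_um == 0).all(axis=1))   # pinned centre

    def test_rejects_non_positive_inputs(self):
        with pytest.raises(ValueError):
            make_scan_grid(0, 1.0)
        with pytest.raises(ValueError):
            make_scan_grid(10, -1.0)


class TestAcquisitionTiming:
    def test_frame_and_volume_times(self):
        t = acquisition_timing(31500, 1, 22700)
        assert t["frame_time_s"] == pytest.approx(1.39, abs=0.01)
        t = acquisition_timing(7850, 21, 22700)
        assert t["volume_time_s"] == pytest.approx(7.26, abs=0.01)
        assert t["frame_rate_fps"] == pytest.approx(2.89, abs=0.01)

    def test_zero_positions(self):
        assert acquisition_timing(0, 1, 22700)["frame_time_s"] == 0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            acquisition_timing(100, 1, 0)


class TestCharacteriseAllPlanes:
    def test_two_plane_stack_matches_oracles(self):
        stack = generate_tm_stack([0, 5], 16, (6, 6), seed=8)
        ps = build_hadamard_pattern_set(16)
        rvs = characterise_all_planes(stack, ps)
        assert [rv.plane_z_um for rv in rvs] == [0, 5]
        for tm, rv in zip(stack, rvs):
            ora = analytic_rvitm_oracle(tm).matrix
            err = np.linalg.norm(rv.matrix - ora) / np.linalg.norm(ora)
            assert err <= 1e-9
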