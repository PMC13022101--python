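import numpy as np
import pytest

from rmsx import (
    DegenerateInputError,
    Event,
    MetricMatrix,
    RmsxError,
    SlicingError,
    SyntheticSpec,
    build_system,
    classic_rmsf,
    compute_rmsx,
    expected_rmsf,
    lddt_series,
    mean_rmsx_per_residue,
    mean_rmsx_per_slice,
    pearson,
    plan_slices,
    select_atoms,
    shift_map,
    window_check,
    window_rmsf,
)
from rmsx.metrics import average_per_slice
from rmsx.structure_io import TrajectorySystem

from _oracles import brute_force_lddt, direct_pearson, random_rigid_transform


def _clone(system, coords):
    return TrajectorySystem(
        names=system.names, resids=system.resids, resnames=system.resnames,
        chain_ids=system.chain_ids, elements=system.elements,
        coords=coords, dt_ps=system.dt_ps,
    )


class TestWindowRmsf:
    def test_identical_frames_zero(self):
        system = build_system(SyntheticSpec(n_residues=6, n_frames=10, sigma=0.0, seed=0))
        sel = select_atoms(system)
        np.testing.assert_allclose(window_rmsf(system.coords, sel), 0.0, atol=1e-12)

    def test_two_frame_closed_form(self):
        system = build_system(SyntheticSpec(n_residues=5, n_frames=2, sigma=0.0, seed=0))
        coords = system.coords.copy()
        coords[0, 2, 0] += 1.0
        coords[1, 2, 0] -= 1.0
        values = window_rmsf(coords, select_atoms(system))
        expected = np.zeros(5)
        expected[2] = 1.0
        np.testing.assert_allclose(values, expected, atol=1e-12)

    def test_gaussian_jitter_analytic(self):
        spec = SyntheticSpec(n_residues=10, n_frames=10_000, sigma=0.5, seed=42)
        system = build_system(spec)
        values = window_rmsf(system.coords, select_atoms(system))
        np.testing.assert_allclose(values, 0.5 * np.sqrt(3.0), rtol=0.02)

    def test_single_frame_rejected(self, jitter_system, ca_selection):
        with pytest.raises(SlicingError, match="window too short"):
            window_rmsf(jitter_system.coords[:1], ca_selection)


class TestComputeRmsx:
    def test_single_slice_equals_classic_rmsf(self, jitter_system, ca_selection):
        plan = plan_slices(jitter_system.n_frames, n_slices=1,
                           dt_ps=jitter_system.dt_ps)
        column = compute_rmsx(jitter_system, plan, ca_selection).values[:, 0]
        np.testing.assert_allclose(
            column, classic_rmsf(jitter_system, ca_selection), atol=1e-12
        )

    def test_event_localized(self):
        spec = SyntheticSpec(
            n_residues=30, n_frames=400, sigma=0.2, seed=17,
            events=(Event(10, 13, 200, 320, 10.0),),
        )
        system = build_system(spec)
        sel = select_atoms(system)
        plan = plan_slices(400, n_slices=10, dt_ps=spec.dt_ps)
        matrix = compute_rmsx(system, plan, sel)
        # event frames 200-320 cover slices 5, 6, 7 (40-frame windows)
        for row in range(10, 13):
            assert int(np.argmax(matrix.values[row])) in {5, 6, 7}

    def test_stationary_columns_agree(self, jitter_system, ca_selection):
        plan = plan_slices(jitter_system.n_frames, n_slices=4,
                           dt_ps=jitter_system.dt_ps)
        matrix = compute_rmsx(jitter_system, plan, ca_selection, align_mode="none")
        expected = 0.5 * np.sqrt(3.0)
        # T = 100 frames per slice: sampling error ~ sigma/sqrt(2T) per cell
        np.testing.assert_allclose(matrix.values, expected, rtol=0.15)

    def test_offset_invariance(self, jitter_system, ca_selection):
        plan = plan_slices(jitter_system.n_frames, n_slices=5,
                           dt_ps=jitter_system.dt_ps)
        moved = _clone(jitter_system, jitter_system.coords + [3.0, -4.0, 12.0])
        a = compute_rmsx(jitter_system, plan, ca_selection, align_mode="none")
        b = compute_rmsx(moved, plan, select_atoms(moved), align_mode="none")
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_matrix_dimensions_and_labels(self, jitter_system, ca_selection):
        plan = plan_slices(jitter_system.n_frames, n_slices=8,
                           dt_ps=jitter_system.dt_ps)
        matrix = compute_rmsx(jitter_system, plan, ca_selection)
        assert matrix.values.shape == (10, 8)
        assert len(matrix.time_edges_ns) == 9
        assert matrix.residue_labels == ca_selection.residue_keys

    def test_window_align_mode_runs(self, jitter_system, ca_selection):
        plan = plan_slices(jitter_system.n_frames, n_slices=4,
                           dt_ps=jitter_system.dt_ps)
        matrix = compute_rmsx(jitter_system, plan, ca_selection, align_mode="window")
        assert np.all(matrix.values >= 0)


class TestClassicRmsf:
    def test_constant_trajectory_zero(self):
        system = build_system(SyntheticSpec(n_residues=5, n_frames=20, sigma=0.0, seed=0))
        np.testing.assert_allclose(
            classic_rmsf(system, select_atoms(system)), 0.0, atol=1e-12
        )

    def test_sinusoid_analytic(self):
        spec = SyntheticSpec(
            n_residues=8, n_frames=400, sigma=0.0,
            sinusoid_amplitude=2.0, sinusoid_period=40, seed=0,
        )
        system = build_system(spec)
        values = classic_rmsf(system, select_atoms(system), align_mode="none")
        np.testing.assert_allclose(values, 2.0 / np.sqrt(2.0), rtol=0.01)
        np.testing.assert_allclose(values, expected_rmsf(spec), rtol=0.01)


class TestMeans:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        labels = [("A", i + 1, "ALA") for i in range(values.shape[0])]
        edges = np.arange(values.shape[1] + 1, dtype=float)
        return MetricMatrix(kind="rmsx", values=values,
                            residue_labels=labels, time_edges_ns=edges)

    def test_two_by_two(self):
        matrix = self._matrix([[1, 3], [2, 4]])
        np.testing.assert_allclose(mean_rmsx_per_residue(matrix), [2.0, 3.0])
        np.testing.assert_allclose(mean_rmsx_per_slice(matrix), [1.5, 3.5])

    def test_single_slice_identity(self):
        matrix = self._matrix([[1.0], [2.5], [0.25]])
        np.testing.assert_allclose(
            mean_rmsx_per_residue(matrix), matrix.values[:, 0]
        )

    def test_constant_matrix(self):
        matrix = self._matrix(np.full((3, 4), 0.7))
        np.testing.assert_allclose(mean_rmsx_per_residue(matrix), 0.7)
        np.testing.assert_allclose(mean_rmsx_per_slice(matrix), 0.7)

    def test_kind_checked(self, jitter_system, ca_selection):
        shift = shift_map(jitter_system, ca_selection)
        with pytest.raises(RmsxError):
            mean_rmsx_per_residue(shift)


class TestShiftMap:
    def test_reference_column_zero(self, jitter_system, ca_selection):
        matrix = shift_map(jitter_system, ca_selection, reference_frame=3)
        np.testing.assert_allclose(matrix.values[:, 3], 0.0, atol=1e-12)

    def test_translation_pythagoras_no_align(self):
        base = build_system(SyntheticSpec(n_residues=6, n_frames=1, sigma=0.0, seed=1))
        coords = np.concatenate([base.coords, base.coords + [3.0, 4.0, 0.0]])
        system = _clone(base, coords)
        matrix = shift_map(system, select_atoms(system), align=False)
        np.testing.assert_allclose(matrix.values[:, 1], 5.0, atol=1e-12)

    def test_translation_removed_with_align(self):
        base = build_system(SyntheticSpec(n_residues=6, n_frames=1, sigma=0.0, seed=1))
        coords = np.concatenate([base.coords, base.coords + [3.0, 4.0, 0.0]])
        system = _clone(base, coords)
        matrix = shift_map(system, select_atoms(system), align=True)
        np.testing.assert_allclose(matrix.values[:, 1], 0.0, atol=1e-9)

    def test_drift_monotonic_while_rmsx_flat(self):
        # drift slow relative to the window: per-window ramp std
        # drift * T / sqrt(12) = 0.058 Å << sigma * sqrt(3) = 0.35 Å
        drift_spec = SyntheticSpec(
            n_residues=10, n_frames=1000, sigma=0.2,
            drift=(0.002, 0.0, 0.0), seed=23,
        )
        still_spec = SyntheticSpec(n_residues=10, n_frames=1000, sigma=0.2, seed=23)
        drifting = build_system(drift_spec)
        still = build_system(still_spec)
        sel = select_atoms(drifting)

        matrix = shift_map(drifting, sel, align=False)
        mean_shift = matrix.values.mean(axis=0)
        # smooth out jitter: per-100-frame means must increase strictly
        blocks = mean_shift.reshape(10, 100).mean(axis=1)
        assert np.all(np.diff(blocks) > 0)
        # final displacement ~ drift * 999 plus noise of order sigma*sqrt(2)
        assert matrix.values[:, -1].mean() == pytest.approx(0.002 * 999, rel=0.1)

        plan = plan_slices(1000, n_slices=10, dt_ps=10)
        rmsx_drift = compute_rmsx(drifting, plan, sel, align_mode="none").values
        rmsx_still = compute_rmsx(still, plan, select_atoms(still),
                                  align_mode="none").values
        assert np.all(
            np.abs(rmsx_drift.mean(axis=1) - rmsx_still.mean(axis=1))
            <= 0.1 * rmsx_still.mean(axis=1)
        )


class TestLddtSeries:
    def test_self_reference_scores_one(self, jitter_system, ca_selection):
        matrix = lddt_series(jitter_system, ca_selection, reference_frame=2)
        np.testing.assert_allclose(matrix.values[:, 2], 1.0)

    def test_rigid_transform_scores_one(self, rng):
        base = build_system(SyntheticSpec(n_residues=12, n_frames=1, sigma=0.0, seed=6))
        rot, shift = random_rigid_transform(rng)
        coords = np.concatenate([base.coords, base.coords[:1] @ rot.T + shift])
        system = _clone(base, coords)
        matrix = lddt_series(system, select_atoms(system), reference_frame=0)
        np.testing.assert_allclose(matrix.values, 1.0, atol=1e-12)

    def test_displaced_residue_matches_brute_force(self):
        base = build_system(SyntheticSpec(n_residues=5, n_frames=1, sigma=0.0, seed=8))
        displaced = base.coords[0].copy()
        displaced[2] += [0.0, 0.0, 10.0]
        system = _clone(base, np.stack([base.coords[0], displaced]))
        sel = select_atoms(system)
        matrix = lddt_series(system, sel, reference_frame=0, r0=15.0,
                             thresholds=(0.5, 1.0, 2.0, 4.0))
        oracle = brute_force_lddt(
            base.coords[0], displaced, np.arange(5), 15.0, (0.5, 1.0, 2.0, 4.0)
        )
        np.testing.assert_array_equal(matrix.values[:, 1], oracle)

    def test_isolated_residue_is_nan_not_zero(self):
        base = build_system(SyntheticSpec(n_residues=4, n_frames=2, sigma=0.0, seed=0))
        coords = base.coords.copy()
        coords[:, 3] += [500.0, 0.0, 0.0]  # beyond every R0 pairing
        system = _clone(base, coords)
        matrix = lddt_series(system, select_atoms(system), r0=10.0)
        assert np.isnan(matrix.values[3]).all()
        assert np.isfinite(matrix.values[:3]).all()

    def test_thresholds_validated(self, jitter_system, ca_selection):
        with pytest.raises(RmsxError):
            lddt_series(jitter_system, ca_selection, thresholds=(4.0, 1.0))
        with pytest.raises(RmsxError):
            lddt_series(jitter_system, ca_selection, r0=-1.0)

    def test_average_per_slice(self, jitter_system, ca_selection):
        matrix = lddt_series(jitter_system, ca_selection)
        plan = plan_slices(jitter_system.n_frames, n_slices=4,
                           dt_ps=jitter_system.dt_ps)
        avg = average_per_slice(matrix, plan)
        assert avg.values.shape == (10, 4)
        lo, hi = plan.slice_bounds[1]
        np.testing.assert_allclose(
            avg.values[:, 1], matrix.values[:, lo:hi].mean(axis=1)
        )


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, r2 = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r, r2 = pearson(x, y)
        assert r == pytest.approx(direct_pearson(x, y), abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-12)

    def test_degenerate_series(self):
        with pytest.raises(DegenerateInputError, match="degenerate"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 2.0], [2.0, 1.0])


class TestWindowCheck:
    def test_forced_drift_couples_rmsx_and_rmsd(self):
        spec = SyntheticSpec(
            n_residues=12, n_frames=1024, sigma=0.1,
            events=(
                Event(0, 12, 256, 512, 4.0),
                Event(0, 12, 512, 768, 8.0),
                Event(0, 12, 768, 1024, 16.0),
            ),
            seed=31,
        )
        system = build_system(spec)
        report = window_check(system, select_atoms(system), (8, 16))
        for entry in report.entries:
            assert not entry.skipped
            assert entry.pearson_r > 0.8

    def test_slow_internal_deformation_decoupled(self):
        # slow non-rigid deformation (quadratic profile along the chain, so a
        # rigid fit cannot absorb it) ramps RMSD monotonically while the
        # within-window fluctuation stays at the flat noise baseline; the
        # per-slice means then decorrelate
        spec = SyntheticSpec(n_residues=12, n_frames=1024, sigma=0.3, seed=37)
        system = build_system(spec)
        profile = (np.arange(12) - 5.5) ** 2 / 30.25  # 0..1, quadratic
        ramp = np.linspace(0.0, 4.0, 1024)
        coords = system.coords.copy()
        coords[:, :, 2] += ramp[:, None] * profile[None, :]
        system = _clone(system, coords)
        report = window_check(system, select_atoms(system), (64,))
        (entry,) = report.entries
        assert not entry.skipped
        assert abs(entry.pearson_r) < 0.3

    def test_oversized_candidate_skipped(self):
        spec = SyntheticSpec(n_residues=8, n_frames=100, sigma=0.2, seed=5)
        system = build_system(spec)
        report = window_check(system, select_atoms(system), (4, 128))
        by_count = {e.n_slices: e for e in report.entries}
        assert not by_count[4].skipped
        assert by_count[128].skipped

    def test_r_squared_consistent(self):
        spec = SyntheticSpec(n_residues=8, n_frames=512, sigma=0.25, seed=3)
        system = build_system(spec)
        report = window_check(system, select_atoms(system), (4, 8, 16))
        for entry in report.entries:
            if not entry.skipped:
                assert entry.r_squared == pytest.approx(entry.pearson_r**2, abs=1e-12)
                assert -1.0 <= entry.pearson_r <= 1.0
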