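import numpy as np
import pytest

from fidsnav import (
    FieldEstimate,
    RigidTransform,
    correct_snav_phase,
    estimate_field_shift,
    estimate_rotation,
    estimate_translation,
    simulate_snav,
)
from fidsnav.estimation import combine_channels_magnitude
from fidsnav.navigator import simulate_fid


class TestFieldShift:
    def test_identical_fid_gives_zero(self, small_phantom, small_coils,
                                      small_protocol):
        fid = simulate_fid(small_phantom, small_coils, protocol=small_protocol)
        est = estimate_field_shift(fid, fid, small_protocol)
        assert est.valid
        assert np.allclose(est.df0_hz, 0.0, atol=1e-12)

    def test_exact_ramp_recovery(self, small_phantom, small_coils,
                                 small_protocol):
        ref = simulate_fid(small_phantom, small_coils, protocol=small_protocol)
        fid = simulate_fid(small_phantom, small_coils,
                           df0_per_channel=[5.0, -2.5, 0.0, 11.25],
                           protocol=small_protocol)
        est = estimate_field_shift(fid, ref, small_protocol)
        assert np.allclose(est.df0_hz, [5.0, -2.5, 0.0, 11.25], atol=1e-6)

    def test_discard_window_robustness(self, small_phantom, small_coils,
                                       small_protocol):
        """The first 15 FID points may behave arbitrarily without biasing
        the fit."""
        ref = simulate_fid(small_phantom, small_coils, protocol=small_protocol)
        fid = simulate_fid(small_phantom, small_coils,
                           df0_per_channel=[5.0] * 4, protocol=small_protocol)
        fid[:, :15] = 99.0 - 3j
        est = estimate_field_shift(fid, ref, small_protocol)
        assert np.allclose(est.df0_hz, 5.0, atol=1e-6)

    def test_static_phase_offsets_cancel(self, small_phantom, small_coils,
                                         small_protocol):
        """Eddy-current-like static per-channel phase is absorbed by the
        reference normalisation."""
        offs = np.array([0.3, -1.2, 2.0, 0.7])
        ref = simulate_fid(small_phantom, small_coils, protocol=small_protocol,
                           phase_offset_rad=offs)
        fid = simulate_fid(small_phantom, small_coils,
                           df0_per_channel=[3.0] * 4,
                           protocol=small_protocol, phase_offset_rad=offs)
        est = estimate_field_shift(fid, ref, small_protocol)
        assert np.allclose(est.df0_hz, 3.0, atol=1e-6)

    def test_zero_reference_points_excluded(self, small_phantom, small_coils,
                                            small_protocol):
        ref = simulate_fid(small_phantom, small_coils, protocol=small_protocol)
        fid = simulate_fid(small_phantom, small_coils,
                           df0_per_channel=[5.0] * 4, protocol=small_protocol)
        ref[:, 20:26] = 0.0
        est = estimate_field_shift(fid, ref, small_protocol)
        assert est.valid
        assert np.allclose(est.df0_hz, 5.0, atol=1e-6)

    def test_too_few_points_invalid(self, small_phantom, small_coils,
                                    small_protocol):
        ref = simulate_fid(small_phantom, small_coils, protocol=small_protocol)
        fid = ref.copy()
        ref2 = ref.copy()
        ref2[:, 15:-5] = 0.0  # only 5 usable points remain
        est = estimate_field_shift(fid, ref2, small_protocol)
        assert not est.valid


class TestSnavPhaseCorrection:
    def test_zero_shift_is_identity(self, small_phantom, small_coils,
                                    nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, trajectory=nav_trajectory)
        est = FieldEstimate(np.zeros(4), np.zeros(4), 8)
        assert np.array_equal(correct_snav_phase(s, est, 3e-3), s)

    def test_corrupt_then_correct_roundtrip(self, small_phantom, small_coils,
                                            nav_trajectory):
        df0 = np.array([10.0, -4.0, 2.5, 0.0])
        t_nav = 3e-3
        clean = simulate_snav(small_phantom, small_coils,
                              trajectory=nav_trajectory)
        shifted = simulate_snav(small_phantom, small_coils,
                                df0_per_channel=df0, trajectory=nav_trajectory,
                                nav_time_s=t_nav)
        est = FieldEstimate(df0, np.zeros(4), 8)
        assert np.allclose(correct_snav_phase(shifted, est, t_nav), clean,
                           rtol=1e-12)

    def test_plus_minus_composition_is_identity(self, small_phantom,
                                                small_coils, nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, trajectory=nav_trajectory)
        plus = FieldEstimate(np.full(4, 7.0), np.zeros(4), 8)
        minus = FieldEstimate(np.full(4, -7.0), np.zeros(4), 8)
        back = correct_snav_phase(correct_snav_phase(s, plus, 3e-3), minus, 3e-3)
        assert np.allclose(back, s, rtol=1e-12)

    def test_invalid_estimate_passes_through(self, small_phantom, small_coils,
                                             nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, trajectory=nav_trajectory)
        est = FieldEstimate(np.full(4, 3.0), np.zeros(4), 8, valid=False)
        with pytest.warns(UserWarning):
            out = correct_snav_phase(s, est, 3e-3)
        assert np.array_equal(out, s)


class TestLookupTable:
    def test_node_identity(self, small_lookup, small_baselines):
        for node in [(0, 0), (3, -2), (-6, 6)]:
            entry = small_lookup.entry(node[0], node[1], 0.0)
            mag = combine_channels_magnitude(
                small_baselines.record(*node).snav)
            assert np.allclose(entry, mag, rtol=1e-5)

    def test_grid_extent_49_per_axis(self, small_lookup):
        assert small_lookup.n_grid == 49
        assert small_lookup.grid_angles[0] == -6.0
        assert small_lookup.grid_angles[-1] == 6.0
        assert np.allclose(np.diff(small_lookup.grid_angles), 0.25)

    def test_z_entry_matches_simulation_oracle(self, small_lookup,
                                               small_phantom, small_coils,
                                               nav_trajectory):
        """entry(0, 0, tz) must track an independently simulated navigator
        rotated about z (trajectory angle tz = -head angle)."""
        for head_z in (2.0, -3.5):
            s = simulate_snav(small_phantom, small_coils,
                              RigidTransform((0, 0, head_z)),
                              trajectory=nav_trajectory)
            mag = combine_channels_magnitude(s)
            entry = small_lookup.entry(0.0, 0.0, -head_z)
            corr = np.corrcoef(mag, entry)[0, 1]
            assert corr > 0.999

    def test_incomplete_grid_rejected(self, small_baselines):
        from fidsnav.navigator import BaselineSet

        partial = dict(list(small_baselines.records.items())[:-1])
        with pytest.raises(ValueError):
            BaselineSet(small_baselines.angles_deg, partial,
                        small_baselines.reference_fid,
                        small_baselines.trajectory)


class TestRotation:
    def test_identity_pose(self, small_phantom, small_coils, small_lookup,
                           nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, trajectory=nav_trajectory,
                          dtype=np.complex64)
        rot, resid, oor = estimate_rotation(combine_channels_magnitude(s),
                                            small_lookup)
        assert rot == (0.0, 0.0, 0.0)
        assert not oor

    @pytest.mark.parametrize("true_rot", [(2.0, -3.0, 1.0), (1.3, 0.6, -2.2),
                                          (-4.9, 4.1, 3.7)])
    def test_forward_simulation_recovery(self, true_rot, small_phantom,
                                         small_coils, small_lookup,
                                         nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, RigidTransform(true_rot),
                          trajectory=nav_trajectory, dtype=np.complex64)
        rot, _, _ = estimate_rotation(combine_channels_magnitude(s),
                                      small_lookup)
        assert np.all(np.abs(np.array(rot) - true_rot) <= 0.25)

    def test_out_of_range_flag(self, small_phantom, small_coils, small_lookup,
                               nav_trajectory):
        s = simulate_snav(small_phantom, small_coils,
                          RigidTransform((0, 0, 7.0)),
                          trajectory=nav_trajectory, dtype=np.complex64)
        _, _, oor = estimate_rotation(combine_channels_magnitude(s),
                                      small_lookup)
        assert oor

    def test_coarse_to_fine_matches_full_search(self, small_phantom,
                                                small_coils, small_lookup,
                                                nav_trajectory):
        s = simulate_snav(small_phantom, small_coils,
                          RigidTransform((2.6, -1.4, 3.1)),
                          trajectory=nav_trajectory, dtype=np.complex64)
        mag = combine_channels_magnitude(s)
        fast = estimate_rotation(mag, small_lookup)
        full = estimate_rotation(mag, small_lookup, full_search=True)
        assert fast[0] == full[0]

    def test_degenerate_input_rejected(self, small_lookup):
        with pytest.raises(ValueError):
            estimate_rotation(np.zeros(960), small_lookup)


class TestTranslation:
    def test_zero_translation(self, small_phantom, small_coils,
                              small_baselines, nav_trajectory):
        s = simulate_snav(small_phantom, small_coils, trajectory=nav_trajectory,
                          dtype=np.complex64)
        t, resid, low = estimate_translation(s, small_baselines,
                                             nav_trajectory, (0, 0, 0))
        assert np.allclose(t, 0.0, atol=1e-6)
        assert not low

    def test_pure_translation_recovery(self, small_phantom, small_coils,
                                       small_baselines, nav_trajectory):
        true_t = (1.2, -0.8, 0.5)
        s = simulate_snav(small_phantom, small_coils,
                          RigidTransform((0, 0, 0), true_t),
                          trajectory=nav_trajectory)
        t, _, _ = estimate_translation(s, small_baselines, nav_trajectory,
                                       (0, 0, 0))
        assert np.all(np.abs(np.array(t) - true_t) <= 0.05)

    def test_analytic_phase_ramp_exact(self, small_baselines, nav_trajectory):
        """A synthetic ramp injected on the baseline itself must invert to
        machine precision (pure least squares, no model error)."""
        true_t_mm = np.array([0.0, 0.0, 2.0])
        ref = small_baselines.record(0, 0).snav
        ramp = np.exp(-2j * np.pi * (nav_trajectory.points @ (true_t_mm / 10)))
        s = ref * ramp[None, :]
        t, resid, _ = estimate_translation(s, small_baselines, nav_trajectory,
                                           (0, 0, 0))
        assert np.allclose(t, true_t_mm, atol=1e-9)
        assert resid < 1e-9

    def test_sign_convention(self, small_phantom, small_coils,
                             small_baselines, nav_trajectory):
        # +x object shift yields +tx
        s = simulate_snav(small_phantom, small_coils,
                          RigidTransform((0, 0, 0), (2.0, 0, 0)),
                          trajectory=nav_trajectory)
        t, _, _ = estimate_translation(s, small_baselines, nav_trajectory,
                                       (0, 0, 0))
        assert t[0] > 1.9


class TestEndToEnd:
    def test_noiseless_pose_recovery(self, small_phantom, small_coils,
                                     small_baselines, small_lookup,
                                     nav_trajectory):
        """Randomised rotation+translation recovery on the desk phantom."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            rot = tuple(rng.uniform(-5.75, 5.75, 3))
            tr = tuple(rng.uniform(-5, 5, 3))
            s = simulate_snav(small_phantom, small_coils,
                              RigidTransform(rot, tr),
                              trajectory=nav_trajectory, dtype=np.complex64)
            r_est, _, _ = estimate_rotation(combine_channels_magnitude(s),
                                            small_lookup)
            t_est, _, _ = estimate_translation(s, small_baselines,
                                               nav_trajectory, r_est)
            assert np.all(np.abs(np.array(r_est) - rot) <= 0.25)
            assert np.all(np.abs(np.array(t_est) - tr) <= 0.2)

    def test_field_motion_decoupling(self, small_phantom, small_coils,
                                     small_protocol, small_baselines,
                                     small_lookup, nav_trajectory):
        """Adding a uniform df0 changes the field estimate by exactly that
        amount and the motion estimate (after phase correction) not at all."""
        pose = RigidTransform((1.5, -2.0, 0.75), (1.0, 0.5, -0.5))
        t_nav = small_protocol.snav_time_ms / 1e3
        ref_fid = simulate_fid(small_phantom, small_coils,
                               protocol=small_protocol)
        results = []
        for df0 in (0.0, 8.0):
            fid = simulate_fid(small_phantom, small_coils, pose,
                               [df0] * 4, small_protocol)
            snav = simulate_snav(small_phantom, small_coils, pose, [df0] * 4,
                                 nav_trajectory, nav_time_s=t_nav)
            fest = estimate_field_shift(fid, ref_fid, small_protocol)
            corr = correct_snav_phase(snav, fest, t_nav)
            rot, _, _ = estimate_rotation(combine_channels_magnitude(corr),
                                          small_lookup)
            tr, _, _ = estimate_translation(corr, small_baselines,
                                            nav_trajectory, rot)
            results.append((fest.df0_hz.copy(), rot, np.array(tr)))
        assert np.allclose(results[1][0] - results[0][0], 8.0, atol=1e-6)
        assert results[0][1] == results[1][1]
        assert np.allclose(results[0][2], results[1][2], atol=1e-6)

    def test_true_node_is_global_minimum(self, small_phantom, small_coils,
                                         small_lookup, nav_trajectory):
        """Exhaustive residual scan over the 1 deg sub-grid: the true node
        must be the global minimum for noiseless input."""
        true = (2.0, -1.0, 3.0)
        s = simulate_snav(small_phantom, small_coils, RigidTransform(true),
                          trajectory=nav_trajectory, dtype=np.complex64)
        mag = combine_channels_magnitude(s)
        nodes = small_lookup.node_angles
        best, best_sse = None, np.inf
        for tx in nodes:
            for ty in nodes:
                sse = np.sum(
                    (small_lookup.entries_tz(tx, ty, nodes) - mag[None, :]) ** 2,
                    axis=1,
                )
                i = int(np.argmin(sse))
                if sse[i] < best_sse:
                    best_sse, best = sse[i], (-tx, -ty, -nodes[i])
        assert best == true
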