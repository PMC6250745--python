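"""Floating-point CANN dynamics: kernel, rate normalization, bump behavior."""

import numpy as np
import pytest

from canntrack.core import (
    DynamicsParams,
    GridSpec,
    KernelSpec,
    NetworkState,
    build_interaction_kernel,
    firing_rate,
    grid_to_native,
    native_to_grid,
    predict_location,
    run_frame,
    seed_state,
    step,
    toroidal_offset_distance,
    track_sequence,
    update_potential,
)
from canntrack.errors import ConfigurationError, InputError

GRID = GridSpec(30, 30)
KERN = KernelSpec(J0=2 * np.pi * 4.0, a=2.0, R=15)
PARAMS = DynamicsParams(beta=50.0, k=0.5, n_iter=15)


def brute_force_recurrent(r, grid, kernel, beta):
    """Independent oracle: double loop over all neuron pairs with the
    Gaussian weight, CF restriction, and minimum-image toroidal distance."""
    H, W = grid.shape
    h = (kernel.R - 1) // 2
    out = np.zeros_like(r)
    for x in range(H):
        for y in range(W):
            acc = 0.0
            for xp in range(H):
                for yp in range(W):
                    dr = min(abs(x - xp), H - abs(x - xp))
                    dc = min(abs(y - yp), W - abs(y - yp))
                    if dr > h or dc > h:
                        continue  # outside the connection field
                    d2 = dr * dr + dc * dc
                    acc += kernel.peak * np.exp(-d2 / (2 * kernel.a**2)) * r[xp, yp]
            out[x, y] = beta * acc
    return out


class TestKernel:
    def test_center_weight_is_peak(self):
        k = KernelSpec(J0=2 * np.pi, a=1.0, R=5)
        st = build_interaction_kernel(GridSpec(10, 10), k)
        assert st[2, 2] == pytest.approx(1.0)

    def test_gaussian_falloff(self):
        k = KernelSpec(J0=1.0, a=2.0, R=9)
        st = build_interaction_kernel(GridSpec(20, 20), k)
        center = st[4, 4]
        assert st[4 + 2, 4] == pytest.approx(center * np.exp(-0.5))

    def test_reflection_symmetric(self):
        st = build_interaction_kernel(GRID, KERN)
        assert np.allclose(st, st[::-1, :])
        assert np.allclose(st, st[:, ::-1])
        assert np.allclose(st, st.T)

    def test_even_or_oversized_cf_rejected(self):
        with pytest.raises(ConfigurationError):
            KernelSpec(J0=1.0, a=1.0, R=4)
        with pytest.raises(ConfigurationError):
            build_interaction_kernel(GridSpec(8, 8), KernelSpec(J0=1.0, a=1.0, R=9))

    @pytest.mark.parametrize("shape,R", [((8, 8), 5), ((12, 12), 7), ((7, 11), 5)])
    def test_stencil_matches_brute_force_pairs(self, shape, R):
        """Stencil-based recurrent input equals the all-pairs double loop."""
        grid = GridSpec(*shape)
        kernel = KernelSpec(J0=3.0, a=1.7, R=R)
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 1, grid.shape)
        st = build_interaction_kernel(grid, kernel)
        fast = update_potential(r, np.zeros(grid.shape), st, beta=2.0)
        slow = brute_force_recurrent(r, grid, kernel, beta=2.0)
        assert np.allclose(fast, np.maximum(slow, 0.0), rtol=1e-10, atol=1e-12)

    def test_minimum_image_distance_wraps(self):
        g = GridSpec(10, 10)
        assert toroidal_offset_distance(9, 0, g) == 1.0
        assert toroidal_offset_distance(0, -9, g) == 1.0


class TestFiringRate:
    def test_zero_input_convention(self):
        r = firing_rate(np.zeros((4, 4)), k=0.5)
        assert np.all(r == 0)

    def test_single_neuron(self):
        V = np.zeros((3, 3))
        V[1, 1] = 5.0
        r = firing_rate(V, k=0.5)
        assert r[1, 1] == pytest.approx(2.0)  # 25 / (0.5 * 25)
        assert np.count_nonzero(r) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_rates_sum_to_inverse_k(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.uniform(0, 10, (12, 17))
        k = rng.uniform(0.1, 5.0)
        assert firing_rate(V, k).sum() == pytest.approx(1.0 / k, rel=1e-9)


class TestPotentialUpdate:
    def test_zero_everything(self):
        st = build_interaction_kernel(GRID, KERN)
        V = update_potential(np.zeros(GRID.shape), np.zeros(GRID.shape), st, 50.0)
        assert np.all(V == 0)

    def test_relu_clips_negative_stimulus(self):
        st = build_interaction_kernel(GRID, KERN)
        ext = np.zeros(GRID.shape)
        ext[3, 4] = -3.0
        V = update_potential(np.zeros(GRID.shape), ext, st, 50.0)
        assert np.all(V >= 0) and V[3, 4] == 0

    def test_uniform_rate_gives_uniform_potential(self):
        st = build_interaction_kernel(GRID, KERN)
        c = 0.37
        V = update_potential(np.full(GRID.shape, c), np.zeros(GRID.shape), st, 2.0)
        assert np.allclose(V, 2.0 * c * st.sum())

    def test_shape_mismatch_rejected(self):
        st = build_interaction_kernel(GRID, KERN)
        with pytest.raises(InputError):
            update_potential(np.zeros((5, 5)), np.zeros((6, 6)), st, 1.0)


class TestDynamics:
    def test_bump_persists_without_stimulus(self):
        stencil = build_interaction_kernel(GRID, KERN)
        state = seed_state(GRID, KERN, PARAMS, (10, 12), stencil)
        zero = np.zeros(GRID.shape)
        state = run_frame(state, zero, PARAMS, stencil)  # settle
        state = run_frame(state, zero, PARAMS, stencil)  # persist
        assert predict_location(state.r) == (10, 12)

    def test_single_pixel_stimulus_seeds_bump(self):
        stencil = build_interaction_kernel(GRID, KERN)
        stim = np.zeros(GRID.shape)
        stim[7, 21] = 5.0
        state = step(NetworkState.zeros(GRID), stim, PARAMS, stencil)
        assert predict_location(state.r) == (7, 21)

    def test_beta_k_ratio_invariance(self):
        """Scaling (beta, k) by a common factor leaves V bit-identical and
        scales r by the inverse factor."""
        stencil = build_interaction_kernel(GRID, KERN)
        rng = np.random.default_rng(3)
        stims = [rng.normal(0, 2, GRID.shape) for _ in range(3)]
        p1 = DynamicsParams(beta=50.0, k=0.5, n_iter=5)
        p2 = DynamicsParams(beta=500.0, k=5.0, n_iter=5)
        s1 = seed_state(GRID, KERN, p1, (15, 15), stencil)
        s2 = seed_state(GRID, KERN, p2, (15, 15), stencil)
        argmax1, argmax2 = [], []
        for stim in stims:
            s1 = run_frame(s1, stim, p1, stencil)
            s2 = run_frame(s2, stim, p2, stencil)
            assert np.allclose(s1.V, s2.V, rtol=1e-9, atol=1e-12)
            assert np.allclose(s1.r, 10.0 * s2.r)
            argmax1.append(np.argmax(s1.r))
            argmax2.append(np.argmax(s2.r))
        assert argmax1 == argmax2

    def test_translation_equivariance_on_torus(self):
        stencil = build_interaction_kernel(GRID, KERN)
        rng = np.random.default_rng(4)
        stims = [np.abs(rng.normal(0, 2, GRID.shape)) for _ in range(3)]
        dr, dc = 7, 11
        s = seed_state(GRID, KERN, PARAMS, (5, 5), stencil)
        s_shift = seed_state(GRID, KERN, PARAMS, ((5 + dr) % 30, (5 + dc) % 30), stencil)
        for stim in stims:
            s = step(s, stim, PARAMS, stencil)
            s_shift = step(s_shift, np.roll(stim, (dr, dc), axis=(0, 1)),
                           PARAMS, stencil)
            assert np.allclose(np.roll(s.V, (dr, dc), axis=(0, 1)), s_shift.V,
                               rtol=1e-10, atol=1e-12)

    def test_zero_iterations_is_identity(self):
        stencil = build_interaction_kernel(GRID, KERN)
        p0 = DynamicsParams(beta=50.0, k=0.5, n_iter=0)
        state = seed_state(GRID, KERN, p0, (3, 3), stencil)
        out = run_frame(state, np.ones(GRID.shape), p0, stencil)
        assert out is state

    def test_bump_follows_moving_stimulus(self):
        """The argmax trails a linearly moving stimulus with bounded lag."""
        stencil = build_interaction_kernel(GRID, KERN)
        state = seed_state(GRID, KERN, PARAMS, (15, 5), stencil)
        for t in range(1, 9):
            stim = np.zeros(GRID.shape)
            col = 5 + 2 * t
            stim[14:17, col - 1 : col + 2] = 20.0
            state = run_frame(state, stim, PARAMS, stencil)
            row, c = predict_location(state.r)
            assert abs(c - col) <= 2 and abs(row - 15) <= 2


class TestReadout:
    def test_unique_max(self):
        r = np.zeros((10, 20))
        r[7, 12] = 1.0
        assert predict_location(r) == (7, 12)

    def test_tie_breaks_row_major(self):
        r = np.zeros((6, 6))
        r[3, 4] = r[5, 1] = 2.0
        assert predict_location(r) == (3, 4)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 1, (9, 13))
        row, col = predict_location(r)
        r2 = np.roll(r, (4, 6), axis=(0, 1))
        assert predict_location(r2) == ((row + 4) % 9, (col + 6) % 13)

    def test_all_zero_falls_back(self):
        r = np.zeros((8, 8))
        assert predict_location(r, prev=(2, 3)) == (2, 3)
        assert predict_location(r) == (4, 4)  # grid center


class TestTrackSequence:
    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            track_sequence([], (0, 0, 4, 4), GRID, KERN, PARAMS)

    def test_zero_stimuli_keep_initial_center(self):
        boxes = track_sequence(
            [np.zeros(GRID.shape)] * 3, (13.0, 13.0, 4.0, 4.0), GRID, KERN, PARAMS)
        assert np.allclose(boxes, boxes[0])

    def test_static_object_stays_within_two_pixels(self):
        from canntrack import SyntheticSceneConfig, generate_synthetic_video
        from canntrack.cli import RunConfig, make_float_tracker

        cfg = RunConfig(grid_height=30, grid_width=56)
        scene = SyntheticSceneConfig(n_frames=12, speed=(0.0, 0.0),
                                     noise_sigma=2.0, seed=7)
        seq, gt = generate_synthetic_video(scene)
        pred = make_float_tracker(cfg)(seq.frames, tuple(gt.boxes[0]))
        centers = pred[:, :2] + pred[:, 2:] / 2
        gtc = gt.centers()
        # 2 grid neurons = 8 native px at the 4x downscale; static tracking
        # must stay well inside that
        err = np.linalg.norm(centers - gtc, axis=1)
        assert err.max() <= 8.0


class TestCoordinateMapping:
    @pytest.mark.parametrize("scale", [(1.0, 1.0), (4.0, 4.0), (2.5, 3.75)])
    def test_round_trip_identity(self, scale):
        grid = GridSpec(30, 56)
        for loc in [(0, 0), (15, 20), (29, 55)]:
            xy = grid_to_native(loc, scale)
            assert native_to_grid(xy, scale, grid) == loc
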