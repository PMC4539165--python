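"""Metamorphosis core: advection, flow integration, energy, optimization."""

import numpy as np
import pytest
from scipy import ndimage

from lesionmorph import (
    MetamorphosisParams,
    MetamorphosisPath,
    ScalarVolume,
    advect_step,
    apply_known_displacement,
    energy,
    integrate_flow,
    metamorphose,
    multi_target_metamorphose,
)
from lesionmorph.fields import identity_map
from lesionmorph.metamorphosis import JacobianError, _integrate

from conftest import hard_disk, smooth_disk


def _zero_velocity_path(I_frames, spacing=(1.0, 1.0)):
    I = np.asarray(I_frames, dtype=float)
    n = I.shape[0] - 1
    shape = I.shape[1:]
    v = np.zeros((n, len(shape)) + shape)
    return MetamorphosisPath(
        intensities=I,
        velocities=v,
        maps=np.broadcast_to(identity_map(shape), (n + 1, len(shape)) + shape).copy(),
        spacing=spacing,
        dt=1.0 / n,
        momenta=np.zeros_like(v),
    )


# -- advect_step -------------------------------------------------------------


def test_advect_zero_velocity_identity():
    rng = np.random.default_rng(0)
    vol = ScalarVolume(rng.random((16, 16)))
    out = advect_step(vol, np.zeros((2, 16, 16)), 0.5)
    np.testing.assert_array_equal(out.data, vol.data)


def test_advect_flat_field_identity():
    vol = ScalarVolume(np.full((16, 16), 0.7))
    rng = np.random.default_rng(1)
    v = rng.normal(0, 2, (2, 16, 16))
    out = advect_step(vol, v, 0.3)
    np.testing.assert_allclose(out.data, 0.7, atol=1e-12)


def test_advect_linear_ramp_closed_form():
    """I(x) = x under constant velocity c transports to x - c*dt (interior)."""
    x = np.arange(24, dtype=float)
    vol = ScalarVolume(np.tile(x[:, None], (1, 8)))
    v = np.zeros((2, 24, 8))
    v[0] = 1.5
    out = advect_step(vol, v, 0.5)
    expected = vol.data - 1.5 * 0.5
    np.testing.assert_allclose(out.data[1:-1, :], expected[1:-1, :], atol=1e-9)


def test_advect_shape_mismatch_raises():
    with pytest.raises(ValueError):
        advect_step(ScalarVolume(np.zeros((8, 8))), np.zeros((2, 9, 8)), 0.1)


# -- integrate_flow ----------------------------------------------------------


def test_flow_zero_velocity_identity():
    v = np.zeros((4, 2, 12, 12))
    maps = integrate_flow(v)
    np.testing.assert_array_equal(maps[-1], identity_map((12, 12)))


def test_flow_constant_velocity_translation():
    v = np.zeros((8, 2, 20, 20))
    v[:, 0] = 2.0  # mm/unit time, spacing 1 -> 2 voxels over unit time
    maps = integrate_flow(v)
    disp = maps[-1] - identity_map((20, 20))
    np.testing.assert_allclose(disp[0], 2.0, atol=0.25)
    np.testing.assert_allclose(disp[1], 0.0, atol=0.25)


def test_flow_fine_step_oracle():
    """Coarse Euler integration approaches a fine-step reference as dt shrinks."""
    rng = np.random.default_rng(0)
    v0 = np.stack([ndimage.gaussian_filter(rng.normal(0, 1, (32, 32)), 4) for _ in range(2)])
    v0 *= 3.0 / np.abs(v0).max()

    def endpoint(T):
        v = np.broadcast_to(v0, (T,) + v0.shape).copy()
        return _integrate(v, (1.0, 1.0), 1.0 / T)[-1]

    ref = endpoint(128)
    e8 = np.abs(endpoint(8) - ref).max()
    e16 = np.abs(endpoint(16) - ref).max()
    assert e8 < 0.15
    assert e16 < e8  # first-order convergence


def test_flow_folding_raises_jacobian_error():
    # one huge step folds the grid
    v = np.zeros((1, 2, 16, 16))
    v[0, 0] = -40.0 * np.linspace(-1, 1, 16)[:, None]
    with pytest.raises(JacobianError):
        integrate_flow(v)


# -- energy ------------------------------------------------------------------


def test_energy_identity_path_is_zero():
    I = np.broadcast_to(np.random.default_rng(0).random((6, 6)), (4, 6, 6)).copy()
    path = _zero_velocity_path(I)
    assert energy(path, MetamorphosisParams()) == 0.0


def test_energy_photometric_path_matches_hand_sum():
    """v=0, arbitrary intensity path on 4 voxels: U equals a direct summation."""
    rng = np.random.default_rng(3)
    I = rng.random((4, 2, 2))  # T=3 steps on a 2x2 image
    params = MetamorphosisParams(sigma=0.3, n_timesteps=3)
    path = _zero_velocity_path(I)
    dt = 1.0 / 3
    expected = 0.0
    for t in range(3):
        diff = (I[t + 1] - I[t]) / dt
        expected += float(np.sum(diff**2)) * dt / params.sigma**2
    assert energy(path, params) == pytest.approx(expected, rel=1e-12)


def test_energy_sigma_scaling():
    rng = np.random.default_rng(4)
    I = rng.random((3, 4, 4))
    path = _zero_velocity_path(I)
    u1 = energy(path, MetamorphosisParams(sigma=0.2, n_timesteps=2))
    u2 = energy(path, MetamorphosisParams(sigma=0.4, n_timesteps=2))
    assert u1 == pytest.approx(4.0 * u2, rel=1e-12)


# -- metamorphose ------------------------------------------------------------


def test_identity_problem_zero_path():
    img = ScalarVolume(smooth_disk((10, 10), 5, shape=(24, 24)))
    path = metamorphose(img, img, MetamorphosisParams(n_timesteps=4, max_iters=50))
    assert path.converged
    assert path.energy_trace[-1] == pytest.approx(0.0, abs=1e-12)
    assert np.abs(path.velocities).max() == 0.0
    assert path.endpoint_residuals[-1] == 0.0


def test_large_sigma_pure_photometric_limit():
    src = ScalarVolume(smooth_disk((14, 14), 6))
    tgt = ScalarVolume(smooth_disk((17, 14), 6))
    params = MetamorphosisParams(sigma=1e6, n_timesteps=5, max_iters=100)
    path = metamorphose(src, tgt, params)
    kinetic = float(np.sum(path.momenta * path.velocities)) * path.dt
    # fidelity-only reference: the zero-velocity linear photometric path
    lin = np.stack([(1 - t) * src.data + t * tgt.data for t in np.linspace(0, 1, 6)])
    ref = _zero_velocity_path(lin)
    u_fid = energy(ref, params)
    assert u_fid > 0
    assert kinetic < 1e-6 * u_fid


def test_translated_disk_recovery(translated_disk_path):
    """Recovered displacement inside the disk close to the true 2-voxel shift."""
    src, tgt, path = translated_disk_path
    disp = path.displacement_mm()
    inside = hard_disk((15, 14), 4)
    err = np.hypot(disp[0] - 2.0, disp[1])[inside]
    assert err.mean() < 0.5
    # and the recovered flow maps the source onto the target
    warped = apply_known_displacement(src, disp)
    assert np.abs(warped.data - tgt.data)[inside].mean() < 0.05


def test_energy_trace_monotone_and_jacobian_positive(translated_disk_path):
    _, _, path = translated_disk_path
    trace = np.asarray(path.energy_trace)
    assert np.all(np.diff(trace) <= 1e-10 * max(1.0, trace[0]))
    assert path.min_jacobian() > 0


def test_unnormalized_input_rejected():
    img = ScalarVolume(np.full((8, 8), 2.0))
    with pytest.raises(ValueError, match="normalized"):
        metamorphose(img, ScalarVolume(np.zeros((8, 8))), MetamorphosisParams())


def test_grid_mismatch_rejected():
    a = ScalarVolume(np.zeros((8, 8)))
    b = ScalarVolume(np.zeros((8, 9)))
    with pytest.raises(ValueError):
        metamorphose(a, b, MetamorphosisParams())


def test_symmetry_sanity_both_directions_fit():
    a = ScalarVolume(smooth_disk((13, 14), 5))
    b = ScalarVolume(smooth_disk((17, 14), 6))
    params = MetamorphosisParams(n_timesteps=5, max_iters=150)
    p_ab = metamorphose(a, b, params)
    p_ba = metamorphose(b, a, params)
    assert p_ab.endpoint_residuals[-1] <= params.endpoint_tol
    assert p_ba.endpoint_residuals[-1] <= params.endpoint_tol


def test_discretization_consistency():
    src = ScalarVolume(smooth_disk((14, 14), 6))
    d = np.zeros((2, 32, 32))
    d[0] = 2.0
    tgt = apply_known_displacement(src, d)
    u = {}
    for T in (5, 10):
        params = MetamorphosisParams(sigma=0.05, kernel_width_mm=4.0, n_timesteps=T, max_iters=400)
        u[T] = metamorphose(src, tgt, params).energy_trace[-1]
    assert abs(u[5] - u[10]) / u[10] < 0.1


# -- multi-target ------------------------------------------------------------


def test_two_observations_reduce_to_pairwise():
    src = ScalarVolume(smooth_disk((13, 14), 5))
    tgt = ScalarVolume(smooth_disk((15, 14), 5))
    params = MetamorphosisParams(n_timesteps=4, max_iters=100)
    single = metamorphose(src, tgt, params)
    multi = multi_target_metamorphose([src, tgt], params)
    np.testing.assert_allclose(multi.velocities, single.velocities, atol=1e-12)
    assert multi.energy_trace[-1] == pytest.approx(single.energy_trace[-1], rel=1e-12)


def test_three_identical_observations_zero_path():
    img = ScalarVolume(smooth_disk((14, 14), 5))
    params = MetamorphosisParams(n_timesteps=3, max_iters=50)
    path = multi_target_metamorphose([img, img, img], params)
    assert np.abs(path.velocities).max() == 0.0
    assert path.energy_trace[-1] == pytest.approx(0.0, abs=1e-12)


def test_growing_disk_chain_hits_every_observation():
    frames = [ScalarVolume(smooth_disk((14, 14), r)) for r in (4, 5, 6)]
    params = MetamorphosisParams(n_timesteps=4, max_iters=150)
    path = multi_target_metamorphose(frames, params)
    assert len(path.endpoint_residuals) == 3
    for idx, obs in zip(path.observation_indices, frames):
        assert np.abs(path.intensities[idx] - obs.data).max() <= params.endpoint_tol
    trace = np.asarray(path.energy_trace)
    assert np.all(np.diff(trace) <= 1e-10 * max(1.0, trace[0]))


def test_multi_target_needs_two_observations():
    with pytest.raises(ValueError):
        multi_target_metamorphose([ScalarVolume(np.zeros((8, 8)))], MetamorphosisParams())


def test_3d_morph_smoke():
    """3-D grids run through the same operators."""
    shape = (24, 20, 16)
    g = np.indices(shape).astype(float)
    d1 = np.sqrt((g[0] - 8) ** 2 + (g[1] - 10) ** 2 + (g[2] - 8) ** 2)
    src = ScalarVolume(ndimage.gaussian_filter((d1 <= 4).astype(float), 1.0))
    d2 = np.sqrt((g[0] - 9) ** 2 + (g[1] - 10) ** 2 + (g[2] - 8) ** 2)
    tgt = ScalarVolume(ndimage.gaussian_filter((d2 <= 4).astype(float), 1.0))
    params = MetamorphosisParams(n_timesteps=3, max_iters=30, tol=1e-4)
    path = metamorphose(src, tgt, params)
    assert path.min_jacobian() > 0
    assert np.asarray(path.energy_trace)[-1] <= path.energy_trace[0]
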