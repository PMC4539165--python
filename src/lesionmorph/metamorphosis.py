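"""Image metamorphosis: joint geometric + photometric registration.

The model couples a smooth, diffeomorphic deformation with pointwise
intensity change.  A source image ``I_0`` evolves along a discrete path
``I_0, I_1, ..., I_T`` driven by velocity fields ``v_t``; the path is
found by minimizing

    U(I, v) = sum_t |v_t|_V^2 dt  +  (1/sigma^2) sum_t |r_t|_L2^2 dt

where ``r_t = (I_{t+1} - I_t)/dt + grad(I_t) . v_t`` is the residual of
the advection relation (the photometric source term: where transport
alone cannot explain the intensity change, intensity is created or
destroyed at cost ``1/sigma^2``).  ``sigma`` trades deformation
smoothness against photometric change: small ``sigma`` buys geometry,
large ``sigma`` makes the path purely photometric.

The V-norm is realized by a translation-invariant Gaussian kernel ``K``
(width ``kernel_width_mm``) acting on a momentum field ``m``:
``v = K m`` and ``|v|_V^2 = <m, K m> = <m, v>``.  Optimization is an
alternating steepest descent with backtracking: all momenta are updated
with the intensity path held fixed, then the interior intensities with
the velocities fixed.  Endpoint images are pinned to the observations,
so the estimated path fits each observation exactly (up to float
round-off); gradient steps that would break positivity of the Jacobian
of the flow are rejected and the step size halved.

Both 2-D and 3-D grids are supported by the same code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft

from .fields import (
    divergence,
    identity_map,
    jacobian_determinant,
    sample_scalar,
    sample_vector,
    smooth_vector,
    spatial_gradient,
)
from .volume import ScalarVolume

__all__ = [
    "MetamorphosisParams",
    "MetamorphosisPath",
    "JacobianError",
    "advect_step",
    "integrate_flow",
    "energy",
    "metamorphose",
    "multi_target_metamorphose",
]


class JacobianError(RuntimeError):
    """Raised when an integrated flow folds (det J <= 0 somewhere)."""


@dataclass
class MetamorphosisParams:
    """Hyper-parameters of the metamorphosis estimation.

    sigma
        Trade-off weight (> 0, unitless).  Small values penalize
        photometric change and favour deformation.
    kernel_width_mm
        Standard deviation of the Gaussian V-norm kernel, in mm.
    n_timesteps
        Number of uniform time steps per segment on [0, 1].
    max_iters
        Cap on alternating-descent iterations.
    step_size
        Initial gradient step, adapted by backtracking.
    tol
        Relative energy-decrease stopping threshold.
    endpoint_tol
        Maximum allowed max-abs residual to each observation.
    """

    sigma: float = 0.05
    kernel_width_mm: float = 2.0
    n_timesteps: int = 10
    max_iters: int = 500
    step_size: float = 1.0
    tol: float = 1e-6
    endpoint_tol: float = 1e-2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kernel_width_mm <= 0:
            raise ValueError("kernel_width_mm must be > 0")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def kernel_sigma_vox(self, spacing: Sequence[float]) -> tuple[float, ...]:
        return tuple(self.kernel_width_mm / s for s in spacing)


@dataclass
class MetamorphosisPath:
    """A discrete metamorphosis path.

    ``intensities`` has ``n_steps + 1`` frames, ``velocities`` and
    ``momenta`` have ``n_steps`` frames of shape ``(ndim, *grid)`` in mm
    per unit path time, and ``maps`` holds the accumulated forward flow
    ``phi_t`` as voxel-coordinate positions (``maps[0]`` is the identity).
    """

    intensities: np.ndarray  # (n_steps+1, *grid)
    velocities: np.ndarray  # (n_steps, ndim, *grid)
    maps: np.ndarray  # (n_steps+1, ndim, *grid)
    spacing: tuple[float, ...]
    dt: float
    energy_trace: list[float] = field(default_factory=list)
    converged: bool = False
    momenta: np.ndarray | None = None
    endpoint_residuals: list[float] = field(default_factory=list)
    observation_indices: list[int] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.intensities.shape[1:]

    def min_jacobian(self) -> float:
        return float(min(jacobian_determinant(phi).min() for phi in self.maps))

    def displacement_mm(self) -> np.ndarray:
        """End-to-end displacement field phi_T(x) - x, in mm."""
        disp_vox = self.maps[-1] - identity_map(self.grid_shape)
        spac = np.asarray(self.spacing).reshape((-1,) + (1,) * len(self.grid_shape))
        return disp_vox * spac


# ---------------------------------------------------------------------------
# elementary operators


def advect_step(intensity: ScalarVolume, velocity: np.ndarray, dt: float) -> ScalarVolume:
    """Transport an intensity field one step under a velocity field.

    Semi-Lagrangian pull-back: ``I'(x) = I(x - v(x) dt)`` with ``v`` in
    mm per unit time.  This is the pure-transport part of the advection
    relation; the optimizer's photometric residual is added elsewhere.
    """
    if velocity.shape != (intensity.ndim, *intensity.shape):
        raise ValueError("velocity field shape does not match the intensity grid")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    spac = np.asarray(intensity.spacing).reshape((-1,) + (1,) * intensity.ndim)
    disp_vox = velocity * dt / spac
    coords = identity_map(intensity.shape) - disp_vox
    return ScalarVolume(sample_scalar(intensity.data, coords), intensity.spacing)


def _integrate(velocities: np.ndarray, spacing: Sequence[float], dt: float) -> np.ndarray:
    """Forward-Euler flow integration; returns positions (n+1, ndim, *grid)."""
    n = velocities.shape[0]
    grid_shape = velocities.shape[2:]
    spac = np.asarray(spacing).reshape((-1,) + (1,) * len(grid_shape))
    maps = np.empty((n + 1,) + velocities.shape[1:], dtype=float)
    maps[0] = identity_map(grid_shape)
    for t in range(n):
        v_at_phi = sample_vector(velocities[t], maps[t])
        maps[t + 1] = maps[t] + dt * v_at_phi / spac
    return maps


def integrate_flow(
    velocities: np.ndarray, spacing: Sequence[float] | None = None, dt: float | None = None
) -> np.ndarray:
    """Integrate the flow equation ``d(phi)/dt = v(phi)``, ``phi_0 = id``.

    Returns positions of shape ``(n_steps + 1, ndim, *grid)`` in voxel
    coordinates.  Raises :class:`JacobianError` if the final map folds;
    the caller should then reduce the step size or refine the time grid.
    """
    velocities = np.asarray(velocities, dtype=float)
    ndim = velocities.shape[1]
    if spacing is None:
        spacing = (1.0,) * ndim
    if dt is None:
        dt = 1.0 / velocities.shape[0]
    maps = _integrate(velocities, spacing, dt)
    min_det = float(jacobian_determinant(maps[-1]).min())
    if min_det <= 0:
        raise JacobianError(
            f"flow is not diffeomorphic: min det(Jacobian) = {min_det:.3g}; "
            "reduce step_size or increase n_timesteps"
        )
    return maps


def _residuals(I: np.ndarray, v: np.ndarray, dt: float, spacing) -> np.ndarray:
    """Advection residual r_t = (I_{t+1} - I_t)/dt + grad(I_t) . v_t."""
    n = v.shape[0]
    r = np.empty((n,) + I.shape[1:], dtype=float)
    for t in range(n):
        g = spatial_gradient(I[t], spacing)
        r[t] = (I[t + 1] - I[t]) / dt + np.sum(g * v[t], axis=0)
    return r


def _energy_arrays(
    I: np.ndarray, m: np.ndarray, v: np.ndarray, sigma: float, dt: float, spacing
) -> tuple[float, float, float]:
    cell = float(np.prod(spacing))
    kinetic = float(np.sum(m * v)) * dt * cell
    r = _residuals(I, v, dt, spacing)
    fidelity = float(np.sum(r * r)) * dt * cell / sigma**2
    return kinetic + fidelity, kinetic, fidelity


def _momentum_from_velocity(v: np.ndarray, sigma_vox: tuple[float, ...]) -> np.ndarray:
    """Invert v = K m by Fourier division (regularized).

    Only used for externally built paths that carry no momenta; the
    optimizer always stores the momenta it worked with.
    """
    grid_shape = v.shape[2:]
    transfer = np.ones(grid_shape)
    for ax, (n, s) in enumerate(zip(grid_shape, sigma_vox)):
        freq = sp_fft.fftfreq(n)
        t1d = np.exp(-2.0 * (np.pi * freq * s) ** 2)
        shape = [1] * len(grid_shape)
        shape[ax] = n
        transfer = transfer * t1d.reshape(shape)
    transfer = np.maximum(transfer, 1e-8)
    out = np.empty_like(v)
    for i in range(v.shape[0]):
        spec = sp_fft.fftn(v[i])
        out[i] = np.real(sp_fft.ifftn(spec / transfer))
    return out


def energy(path: MetamorphosisPath, params: MetamorphosisParams) -> float:
    """Discrete cost U of a path: kinetic V-norm term plus advection fidelity."""
    v_all = path.velocities
    if path.momenta is not None:
        m_all = path.momenta
    elif not np.any(v_all):
        m_all = np.zeros_like(v_all)
    else:
        m_all = np.stack(
            [_momentum_from_velocity(v, params.kernel_sigma_vox(path.spacing)) for v in v_all]
        )
    total = 0.0
    for seg_I, seg_m, seg_v in _iter_segments(path, m_all):
        u, _, _ = _energy_arrays(seg_I, seg_m, seg_v, params.sigma, path.dt, path.spacing)
        total += u
    return total


def _iter_segments(path: MetamorphosisPath, m_all: np.ndarray):
    """Yield (intensities, momenta, velocities) per observation segment."""
    idx = path.observation_indices or [0, path.n_steps]
    for a, b in zip(idx[:-1], idx[1:]):
        yield path.intensities[a : b + 1], m_all[a:b], path.velocities[a:b]


# ---------------------------------------------------------------------------
# alternating optimization


def _optimize_segment(
    source: np.ndarray,
    target: np.ndarray,
    spacing: tuple[float, ...],
    params: MetamorphosisParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Minimize U for one source->target segment with pinned endpoints.

    Returns (I, m, v, energy_trace, converged) with shapes
    I: (T+1, *grid); m, v: (T, ndim, *grid).
    """
    T = params.n_timesteps
    grid = source.shape
    ndim = len(grid)
    dt = 1.0 / T
    cell = float(np.prod(spacing))
    sig_vox = params.kernel_sigma_vox(spacing)
    sigma2 = params.sigma**2

    # linear-in-time photometric initialization; zero velocity
    # exact at both endpoints, and exactly constant when source == target
    ts = np.linspace(0.0, 1.0, T + 1).reshape((-1,) + (1,) * ndim)
    I = source[None] + ts * (target - source)[None]
    m = np.zeros((T, ndim) + grid)
    v = np.zeros_like(m)

    U, _, _ = _energy_arrays(I, m, v, params.sigma, dt, spacing)
    trace = [U]
    if U == 0.0:
        return I, m, v, trace, True

    step_v = params.step_size
    step_i = params.step_size
    converged = False
    min_step = 1e-14

    for _ in range(params.max_iters):
        U_before = trace[-1]

        # --- velocity update (intensity path fixed) -----------------------
        grads_I = [spatial_gradient(I[t], spacing) for t in range(T)]
        r = _residuals(I, v, dt, spacing)
        g_m = np.empty_like(m)
        for t in range(T):
            force = smooth_vector(r[t] * grads_I[t], sig_vox)
            g_m[t] = (2.0 * v[t] + (2.0 / sigma2) * force) * dt * cell
        gnorm = float(np.max(np.abs(g_m)))
        if gnorm > 0:
            while step_v > min_step:
                m_try = m - step_v * g_m
                v_try = np.stack([smooth_vector(m_try[t], sig_vox) for t in range(T)])
                U_try, _, _ = _energy_arrays(I, m_try, v_try, params.sigma, dt, spacing)
                if np.isfinite(U_try) and U_try < trace[-1]:
                    maps_try = _integrate(v_try, spacing, dt)
                    if jacobian_determinant(maps_try[-1]).min() > 0:
                        m, v = m_try, v_try
                        trace.append(U_try)
                        step_v *= 2.0
                        break
                step_v *= 0.5

        # --- intensity update (velocities fixed) --------------------------
        if T > 1:
            r = _residuals(I, v, dt, spacing)
            g_I = np.zeros_like(I)
            for s in range(1, T):
                g_I[s] = (2.0 / sigma2) * cell * (
                    (r[s - 1] - r[s]) + dt * (-divergence(r[s] * v[s], spacing))
                )
            if np.max(np.abs(g_I)) > 0:
                while step_i > min_step:
                    I_try = I - step_i * g_I
                    U_try, _, _ = _energy_arrays(I_try, m, v, params.sigma, dt, spacing)
                    if np.isfinite(U_try) and U_try < trace[-1]:
                        I = I_try
                        trace.append(U_try)
                        step_i *= 2.0
                        break
                    step_i *= 0.5

        if not np.isfinite(trace[-1]):
            raise FloatingPointError(
                f"energy became non-finite (U={trace[-1]}); sigma={params.sigma}, "
                f"step_v={step_v:.3g}, step_i={step_i:.3g}"
            )
        decrease = U_before - trace[-1]
        if decrease <= params.tol * max(abs(U_before), 1e-30):
            converged = True
            break
        if step_v <= min_step and step_i <= min_step:
            converged = True  # stalled: no further decrease representable
            break

    return I, m, v, trace, converged


def _check_range(arr: np.ndarray, name: str) -> None:
    lo, hi = float(arr.min()), float(arr.max())
    if lo < -1e-6 or hi > 1.0 + 1e-6:
        raise ValueError(
            f"{name} must be normalized to [0, 1] (found range [{lo:.3g}, {hi:.3g}]); "
            "see normalize_images()"
        )


def normalize_images(*arrays: np.ndarray) -> tuple[list[np.ndarray], tuple[float, float]]:
    """Joint min-max normalization of a set of images to [0, 1].

    Returns the rescaled arrays and the (offset, scale) pair so results
    can later be reported in the original units.
    """
    lo = min(float(a.min()) for a in arrays)
    hi = max(float(a.max()) for a in arrays)
    scale = hi - lo
    if scale == 0:
        return [np.zeros_like(a, dtype=float) for a in arrays], (lo, 1.0)
    return [(np.asarray(a, dtype=float) - lo) / scale for a in arrays], (lo, scale)


def metamorphose(
    source: ScalarVolume, target: ScalarVolume, params: MetamorphosisParams
) -> MetamorphosisPath:
    """Estimate the optimal metamorphosis path from source to target.

    Endpoints are pinned to the observations, so the returned path fits
    both exactly; the alternating descent distributes the change between
    the geometric (velocity) and photometric (residual) channels
    according to ``params.sigma``.
    """
    if not source.same_grid(target):
        raise ValueError("source and target must share one grid")
    _check_range(source.data, "source")
    _check_range(target.data, "target")

    I, m, v, trace, converged = _optimize_segment(
        source.data, target.data, source.spacing, params
    )
    dt = 1.0 / params.n_timesteps
    maps = _integrate(v, source.spacing, dt)
    resid = float(np.max(np.abs(I[-1] - target.data)))
    return MetamorphosisPath(
        intensities=I,
        velocities=v,
        maps=maps,
        spacing=source.spacing,
        dt=dt,
        energy_trace=trace,
        converged=converged,
        momenta=m,
        endpoint_residuals=[0.0, resid],
        observation_indices=[0, params.n_timesteps],
    )


def multi_target_metamorphose(
    observations: Sequence[ScalarVolume], params: MetamorphosisParams
) -> MetamorphosisPath:
    """One path through an ordered set of observations.

    Each consecutive pair is solved as a pinned-endpoint segment on its
    own unit time interval; segments concatenate into a single path with
    a continuous accumulated flow.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations")
    first = observations[0]
    for obs in observations[1:]:
        if not first.same_grid(obs):
            raise ValueError("all observations must share one grid")

    T = params.n_timesteps
    dt = 1.0 / T
    seg_results = []
    for a, b in zip(observations[:-1], observations[1:]):
        seg_results.append(_optimize_segment(a.data, b.data, first.spacing, params))

    I_all = [seg_results[0][0]]
    for I, *_ in seg_results[1:]:
        I_all.append(I[1:])  # drop duplicated joint frame
    intensities = np.concatenate(I_all, axis=0)
    momenta = np.concatenate([m for _, m, _, _, _ in seg_results], axis=0)
    velocities = np.concatenate([v for _, _, v, _, _ in seg_results], axis=0)
    maps = _integrate(velocities, first.spacing, dt)

    # per-segment traces summed after padding to equal length, so the
    # combined trace stays non-increasing
    traces = [tr for _, _, _, tr, _ in seg_results]
    L = max(len(tr) for tr in traces)
    padded = [tr + [tr[-1]] * (L - len(tr)) for tr in traces]
    trace = [float(sum(vals)) for vals in zip(*padded)]

    obs_idx = [k * T for k in range(len(observations))]
    residuals = [
        float(np.max(np.abs(intensities[idx] - obs.data)))
        for idx, obs in zip(obs_idx, observations)
    ]
    return MetamorphosisPath(
        intensities=intensities,
        velocities=velocities,
        maps=maps,
        spacing=first.spacing,
        dt=dt,
        energy_trace=trace,
        converged=all(c for *_, c in seg_results),
        momenta=momenta,
        endpoint_residuals=residuals,
        observation_indices=obs_idx,
    )
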